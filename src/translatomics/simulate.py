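"""Synthetic transcriptomes with planted, parameterised ground truth.

The generator emulates the statistical structure of a polysome-profiling
stress experiment: a transcriptome of UTR/ORF/UTR sequences, a gene x
(condition, fraction, replicate) log2-intensity matrix with a planted
condition x fraction interaction for a designated regulon, a Puf3-like
3'UTR element planted in regulon transcripts, RBP target sets with a
controlled overlap with the regulon, and term annotations enriched in the
regulon.  Every generator is a pure function of (params, seed).

Defaults define the benchmark conditions used throughout the test suite:
3000 genes, a 400-gene regulon with a -2 log2 interaction effect, noise
sigma 0.25, 3 replicates per design cell, motif plant rate 0.9 against a
0.05 background, and a 70% regulon overlap of the Puf3-like target set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .features import FAMILIES, STOP_CODONS, CodonWeightTable, reverse_complement
from .io import (
    GeneSetCollection,
    MotifModel,
    RegionTable,
    SequenceRecord,
    write_gene_sets,
)

PUF3_CONSENSUS = "CYUGUAAAUA"


@dataclass
class SimulationParams:
    """All knobs of the synthetic benchmark (see module docstring)."""

    n_genes: int = 3000
    regulon_size: int = 400
    up_regulon_size: int = 200
    # log-normal (meanlog, sdlog) of region lengths; ORF in codons
    utr5_lognorm: tuple[float, float] = (4.0, 0.5)
    utr3_lognorm: tuple[float, float] = (4.7, 0.5)
    orf_codons_lognorm: tuple[float, float] = (5.8, 0.45)
    min_utr_len: int = 12
    max_utr_len: int = 600
    min_orf_codons: int = 40
    max_orf_codons: int = 1200
    plant_rate: float = 0.9
    background_rate: float = 0.05
    codon_bias_tiers: tuple[float, ...] = (0.25, 0.55, 0.85)
    delta: float = -2.0
    up_delta: float = 2.0
    n_replicates: int = 3
    sigma: float = 0.25
    regulon_total_shift: float = 1.0
    rho: float = 0.7
    target_set_size: int | None = None
    n_decoy_sets: int = 6
    decoy_set_size: int = 200
    n_terms: int = 12
    term_size: int = 150
    n_enriched_terms: int = 2
    enriched_term_regulon_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.regulon_size < self.n_genes:
            raise ValueError("regulon_size must lie in (0, n_genes)")
        if self.regulon_size + self.up_regulon_size >= self.n_genes:
            raise ValueError("regulons must not cover the whole gene set")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for rate in (self.plant_rate, self.background_rate, self.rho):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the synthetic files."""

    regulon: list[str]
    true_delta: dict[str, float]
    planted_motifs: dict[str, list[int]]
    up_regulon: list[str] = field(default_factory=list)
    chance_motifs: dict[str, list[int]] = field(default_factory=dict)
    target_sets: dict[str, list[str]] = field(default_factory=dict)
    enriched_terms: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def _sample_length(rng, lognorm, lo, hi) -> int:
    val = int(round(float(rng.lognormal(*lognorm))))
    return int(np.clip(val, lo, hi))


def _random_utr(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def _preferred_codons() -> dict[str, str]:
    """Per-family 'preferred' codon = highest default tAI weight."""
    weights = CodonWeightTable.tai_from_tgcn(CodonWeightTable.default_tgcn())
    return {
        aa: max(fam, key=lambda c: weights[c]) for aa, fam in FAMILIES.items()
    }


def _random_orf(
    rng: np.random.Generator, n_codons: int, bias: float,
    preferred: dict[str, str],
) -> str:
    """AUG + (n_codons - 2) random sense codons + stop; ``bias`` is the
    probability of choosing the family's preferred codon."""
    aas = list(FAMILIES)
    body = []
    for aa in rng.choice(aas, size=n_codons - 2):
        fam = FAMILIES[aa]
        if rng.random() < bias:
            body.append(preferred[aa])
        else:
            body.append(fam[rng.integers(len(fam))])
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "AUG" + "".join(body) + stop


def _instantiate_motif(rng: np.random.Generator, consensus: str) -> str:
    from .io import IUPAC_RNA

    return "".join(
        sorted(IUPAC_RNA[c])[rng.integers(len(IUPAC_RNA[c]))] for c in consensus
    )


def simulate_transcriptome(
    params: SimulationParams,
) -> tuple[list[SequenceRecord], RegionTable, GroundTruth]:
    """Generate sequences, region table and ground truth.

    Regulon 3'UTRs receive one planted Puf3 consensus instance at
    ``plant_rate``; background genes at ``background_rate``.  Codon usage
    is drawn per gene from one of the bias tiers so CAI/fop/tAI vary.
    Chance motif occurrences in unplanted UTRs are scanned and recorded in
    the truth rather than scrubbed.
    """
    rng = np.random.default_rng(params.seed)
    genes = [f"g{i:05d}" for i in range(params.n_genes)]
    picked = rng.choice(
        genes, size=params.regulon_size + params.up_regulon_size, replace=False
    ).tolist()
    regulon = sorted(picked[: params.regulon_size])
    up_regulon = sorted(picked[params.regulon_size:])
    regulon_set = set(regulon)
    up_set = set(up_regulon)
    preferred = _preferred_codons()
    records: list[SequenceRecord] = []
    rows = []
    planted: dict[str, list[int]] = {}
    chance: dict[str, list[int]] = {}
    from .features import _consensus_regex

    motif_re = _consensus_regex(PUF3_CONSENSUS)
    tiers = params.codon_bias_tiers
    for gene in genes:
        u5 = _sample_length(rng, params.utr5_lognorm, params.min_utr_len,
                            params.max_utr_len)
        u3 = _sample_length(rng, params.utr3_lognorm,
                            max(params.min_utr_len, len(PUF3_CONSENSUS)),
                            params.max_utr_len)
        n_codons = _sample_length(rng, params.orf_codons_lognorm,
                                  params.min_orf_codons, params.max_orf_codons)
        bias = tiers[rng.integers(len(tiers))]
        utr5 = _random_utr(rng, u5)
        orf = _random_orf(rng, n_codons, bias, preferred)
        utr3 = _random_utr(rng, u3)
        rate = params.plant_rate if gene in regulon_set else params.background_rate
        if rng.random() < rate:
            instance = _instantiate_motif(rng, PUF3_CONSENSUS)
            pos = int(rng.integers(0, u3 - len(instance) + 1))
            utr3 = utr3[:pos] + instance + utr3[pos + len(instance):]
            planted[gene] = [pos]
        hits = [m.start() for m in motif_re.finditer(utr3)]
        extra = [h for h in hits if h not in planted.get(gene, [])]
        if extra:
            chance[gene] = extra
        records.append(SequenceRecord(gene, utr5 + orf + utr3))
        rows.append((gene, u5, 3 * n_codons, u3))
    table = pd.DataFrame(
        rows, columns=["transcript_id", "utr5_len", "orf_len", "utr3_len"]
    ).set_index("transcript_id")
    truth = GroundTruth(
        regulon=regulon,
        up_regulon=up_regulon,
        true_delta={
            g: (
                params.delta if g in regulon_set
                else params.up_delta if g in up_set
                else 0.0
            )
            for g in genes
        },
        planted_motifs=planted,
        chance_motifs=chance,
        params=asdict(params),
    )
    return records, RegionTable(table), truth


def simulate_expression(
    truth: GroundTruth, params: SimulationParams
) -> ExpressionMatrix:
    """Log2-intensity matrix with the interaction effect planted in the
    stress x polysome cell of regulon genes.

    log2 I = baseline_g + fraction effect + condition effect
             + delta * 1[regulon] * 1[stress] * 1[polysome] + N(0, sigma^2).
    The total fraction additionally carries a baseline shift for both
    translationally regulated gene sets (regulated transcripts tend to be
    abundant) and a per-gene random transcriptional stress response, so
    the transcript-level features carry signal while the transcriptional
    and translational responses stay uncorrelated overall.
    """
    rng = np.random.default_rng(params.seed + 1)
    genes = sorted(truth.true_delta)
    shifted = set(truth.regulon) | set(truth.up_regulon)
    regulon = np.array([g in shifted for g in genes])
    baseline = rng.normal(10.0, 1.0, size=len(genes))
    tx_response = rng.normal(0.0, 0.5, size=len(genes))  # total-fraction shift
    frac_effect = {"total": 0.0, "monosome": -0.2, "polysome": -0.5}
    cond_effect = {"control": 0.0, "stress": -0.3}
    delta = np.array([truth.true_delta[g] for g in genes])

    rows = []
    for cond in ("control", "stress"):
        for frac in ("total", "monosome", "polysome"):
            mean = baseline + frac_effect[frac] + cond_effect[cond]
            if frac == "polysome" and cond == "stress":
                mean = mean + delta
            if frac == "total":
                mean = mean + params.regulon_total_shift * regulon
                if cond == "stress":
                    mean = mean + tx_response
            for rep in range(1, params.n_replicates + 1):
                noise = rng.normal(0.0, params.sigma, size=len(genes))
                rows.append(
                    pd.DataFrame(
                        {
                            "gene": genes,
                            "condition": cond,
                            "fraction": frac,
                            "replicate": rep,
                            "log2_intensity": mean + noise,
                        }
                    )
                )
    return ExpressionMatrix.from_long(pd.concat(rows, ignore_index=True))


def simulate_gene_sets(
    truth: GroundTruth, params: SimulationParams
) -> tuple[GeneSetCollection, GeneSetCollection]:
    """RBP target sets and term annotations with planted structure.

    Returns (targets, terms): a ``Puf3_like`` target set sharing fraction
    ``rho`` of its members with the regulon plus uniform decoy RBP sets;
    and a term collection in which ``n_enriched_terms`` terms draw
    ``enriched_term_regulon_fraction`` of their members from the regulon.
    """
    rng = np.random.default_rng(params.seed + 2)
    genes = sorted(truth.true_delta)
    universe = frozenset(genes)
    regulon = sorted(truth.regulon)
    non_regulon = sorted(set(genes) - set(regulon))
    size = params.target_set_size or params.regulon_size
    if size > len(genes):
        raise ValueError("target set larger than universe")
    n_planted = int(round(params.rho * min(size, len(regulon))))
    members = rng.choice(regulon, size=n_planted, replace=False).tolist()
    # the remainder is drawn uniformly from the rest of the universe, so at
    # rho=0 the whole set is a uniform draw and the regulon overlap follows
    # the hypergeometric null
    remaining = sorted(set(genes) - set(members))
    members += rng.choice(
        remaining, size=size - n_planted, replace=False
    ).tolist()
    sets = {"Puf3_like": frozenset(members)}
    decoy_size = min(params.decoy_set_size, max(1, len(genes) // 5))
    for i in range(params.n_decoy_sets):
        sets[f"decoy_rbp_{i + 1}"] = frozenset(
            rng.choice(genes, size=decoy_size, replace=False)
        )
    targets = GeneSetCollection(sets, universe)

    term_sets = {}
    enriched = []
    term_size = min(params.term_size, max(2, len(genes) // 5))
    for i in range(params.n_terms):
        name = f"term_{i + 1:02d}"
        if i < params.n_enriched_terms:
            n_reg = int(round(params.enriched_term_regulon_fraction * term_size))
            n_reg = min(n_reg, len(regulon))
            members = rng.choice(regulon, size=n_reg, replace=False).tolist()
            members += rng.choice(
                non_regulon, size=term_size - n_reg, replace=False
            ).tolist()
            enriched.append(name)
        else:
            members = rng.choice(
                genes, size=term_size, replace=False
            ).tolist()
        term_sets[name] = frozenset(members)
    terms = GeneSetCollection(term_sets, universe)
    truth.target_sets = {k: sorted(v) for k, v in sets.items()}
    truth.enriched_terms = enriched
    return targets, terms


def export_truth(truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Write machine-readable truth JSON plus a regulon GMT."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)
    gmt_path = outdir / "regulon.gmt"
    write_gene_sets(
        GeneSetCollection({"regulon": frozenset(truth.regulon)}), gmt_path
    )
    return {"truth": truth_path, "regulon_gmt": gmt_path}


def load_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        data = json.load(fh)
    return GroundTruth(**data)


@dataclass
class SimulatedDataset:
    """Everything one benchmark run needs, in memory."""

    records: list[SequenceRecord]
    regions: RegionTable
    expression: ExpressionMatrix
    targets: GeneSetCollection
    terms: GeneSetCollection
    truth: GroundTruth


def simulate_all(params: SimulationParams) -> SimulatedDataset:
    """Run every generator stage from one (params, seed)."""
    records, regions, truth = simulate_transcriptome(params)
    expression = simulate_expression(truth, params)
    targets, terms = simulate_gene_sets(truth, params)
    return SimulatedDataset(records, regions, expression, targets, terms, truth)
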