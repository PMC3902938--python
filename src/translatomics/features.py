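"""Fixed-schema per-mRNA feature vectors.

Each transcript is split into 5'UTR / ORF / 3'UTR and described by a
77-column default schema: region lengths and base composition, GC content
around the start codon, a structural pseudo-energy per region, codon-usage
indices (CAI, fop, tAI), a start-context score (AUG-CAI(r)), amino-acid
composition of the encoded protein, upstream-AUG/uORF/5'UTR-stop counts,
transcript-level expression under control and stress, and a panel of
RNA-binding-protein motif scores (28 motif x region entries, including the
Puf3 element CYUGUAAAUA in the 3'UTR).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _CodonTable
from sklearn.base import BaseEstimator, TransformerMixin

from ._fold import pairing_pseudo_energy
from .io import (
    IUPAC_RNA,
    MotifModel,
    RegionTable,
    SequenceRecord,
    default_motif_panel,
)

logger = logging.getLogger(__name__)

_CODE = _CodonTable.unambiguous_rna_by_id[1]
STOP_CODONS = tuple(_CODE.stop_codons)  # UAA, UAG, UGA
SENSE_CODONS = tuple(sorted(_CODE.forward_table))
AMINO_ACIDS = tuple(sorted(set(_CODE.forward_table.values())))  # 20

#: codons grouped by encoded amino acid
FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if _CODE.forward_table[c] == aa)
    for aa in AMINO_ACIDS
}
_FAMILY_OF = {c: _CODE.forward_table[c] for c in SENSE_CODONS}
_SINGLE_FAMILY = {c for c, aa in _FAMILY_OF.items() if len(FAMILIES[aa]) == 1}

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

MOTIF_LOG_ODDS_FLOOR = -100.0  # sentinel for max_log_odds on too-short regions

#: wobble pairing penalties s (anticodon-base : codon-base), after the
#: standard tAI parameterisation; Watson-Crick pairs carry s = 0.
DEFAULT_WOBBLE_S = {"G:U": 0.41, "I:C": 0.28, "I:A": 0.9999, "U:G": 0.68}


def reverse_complement(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def codons_of(orf: str) -> list[str]:
    if len(orf) % 3:
        raise ValueError("ORF length not divisible by 3")
    return [orf[i: i + 3] for i in range(0, len(orf), 3)]


# ---------------------------------------------------------------------------
# Transcript assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptRecord:
    """One mRNA split into 5'UTR, ORF and 3'UTR (RNA strings)."""

    id: str
    utr5: str
    orf: str
    utr3: str

    @property
    def sequence(self) -> str:
        return self.utr5 + self.orf + self.utr3


def assemble_transcript(
    seq: SequenceRecord,
    lengths: tuple[int, int, int],
    require_utrs: bool = True,
    validate_orf: bool = True,
) -> TranscriptRecord:
    """Cut one sequence into regions according to (utr5, orf, utr3) lengths.

    Raises ValueError when lengths do not tile the sequence, when a UTR is
    empty under ``require_utrs``, or when ``validate_orf`` and the ORF does
    not start with AUG / end with a stop / contains an internal stop.
    """
    u5, orf_len, u3 = lengths
    if u5 + orf_len + u3 != len(seq.sequence):
        raise ValueError(
            f"{seq.id}: region lengths {u5}+{orf_len}+{u3} != "
            f"sequence length {len(seq.sequence)}"
        )
    if require_utrs and (u5 == 0 or u3 == 0):
        raise ValueError(f"{seq.id}: undefined 5' or 3' UTR")
    utr5 = seq.sequence[:u5]
    orf = seq.sequence[u5: u5 + orf_len]
    utr3 = seq.sequence[u5 + orf_len:]
    if validate_orf:
        if orf[:3] != "AUG":
            raise ValueError(f"{seq.id}: ORF does not start with AUG")
        if orf[-3:] not in STOP_CODONS:
            raise ValueError(f"{seq.id}: ORF does not end with a stop codon")
        internal = [c for c in codons_of(orf)[:-1] if c in STOP_CODONS]
        if internal:
            raise ValueError(f"{seq.id}: internal stop codon in ORF")
    return TranscriptRecord(seq.id, utr5, orf, utr3)


def assemble_transcripts(
    seqs: Sequence[SequenceRecord],
    regions: RegionTable,
    require_utrs: bool = True,
    on_invalid: str = "drop",
) -> tuple[list[TranscriptRecord], int]:
    """Assemble all transcripts present in both inputs.

    ``on_invalid='drop'`` drops (and logs) transcripts failing the ORF or
    UTR invariants; ``'error'`` raises on the first failure.  Returns the
    records and the number dropped.
    """
    out: list[TranscriptRecord] = []
    dropped = 0
    for seq in seqs:
        if seq.id not in regions:
            dropped += 1
            continue
        try:
            out.append(
                assemble_transcript(
                    seq, regions.lengths(seq.id), require_utrs=require_utrs
                )
            )
        except ValueError as exc:
            if on_invalid == "error":
                raise
            dropped += 1
            logger.warning("assembly: dropping transcript (%s)", exc)
    return out, dropped


# ---------------------------------------------------------------------------
# Codon weight tables
# ---------------------------------------------------------------------------


@dataclass
class CodonWeightTable:
    """Relative-adaptiveness (CAI), optimal-codon (fop) and tAI weights.

    ``cai_weights`` maps sense codons to w in (0, 1] with max w = 1 per
    synonymous family.  ``optimal_codons`` are the per-family maxima among
    families with a synonymous choice.  ``tai_weights`` are per-codon tRNA
    adaptation weights in (0, 1].
    """

    cai_weights: dict[str, float] = field(default_factory=dict)
    tai_weights: dict[str, float] = field(default_factory=dict)

    @property
    def optimal_codons(self) -> frozenset[str]:
        out = set()
        for aa, fam in FAMILIES.items():
            if len(fam) < 2:
                continue
            ws = [self.cai_weights.get(c, 0.0) for c in fam]
            top = max(ws)
            if top > 0:
                out |= {c for c, w in zip(fam, ws) if w == top}
        return frozenset(out)

    # -- constructors --------------------------------------------------
    @classmethod
    def cai_from_reference(cls, orfs: Iterable[str]) -> dict[str, float]:
        """Relative adaptiveness w_c = usage_c / max usage among synonyms,
        from codon counts of a reference ORF set (0.5 pseudocount)."""
        counts = {c: 0.5 for c in SENSE_CODONS}
        for orf in orfs:
            for codon in codons_of(orf):
                if codon in counts:
                    counts[codon] += 1
        weights: dict[str, float] = {}
        for fam in FAMILIES.values():
            top = max(counts[c] for c in fam)
            for c in fam:
                weights[c] = counts[c] / top
        return weights

    @classmethod
    def tai_from_tgcn(
        cls,
        tgcn: Mapping[str, float],
        s: Mapping[str, float] | None = None,
    ) -> dict[str, float]:
        """tAI weights from tRNA gene copy numbers and wobble penalties.

        The absolute weight of a codon sums (1 - s) * tGCN over the
        anticodons able to read it: the Watson-Crick anticodon plus the
        standard wobble reader of its 4-codon block (G34 reads NNU, inosine
        reads NNC and NNA, U34 reads NNG).  Weights are normalised by the
        maximum; zero weights are imputed with the geometric mean of the
        nonzero weights (standard convention).
        """
        pen = dict(DEFAULT_WOBBLE_S)
        if s is not None:
            pen.update(s)
        tg = {k.upper().replace("T", "U"): float(v) for k, v in tgcn.items()}

        def count(codon: str) -> float:
            return tg.get(reverse_complement(codon), 0.0)

        absolute: dict[str, float] = {}
        for codon in SENSE_CODONS:
            stem = codon[:2]
            third = codon[2]
            if third == "U":
                w = count(codon) + (1 - pen["G:U"]) * count(stem + "C")
            elif third == "C":
                w = count(codon) + (1 - pen["I:C"]) * count(stem + "U")
            elif third == "A":
                w = count(codon) + (1 - pen["I:A"]) * count(stem + "U")
            else:
                w = count(codon) + (1 - pen["U:G"]) * count(stem + "A")
            absolute[codon] = w
        top = max(absolute.values())
        if top <= 0:
            raise ValueError("tGCN table yields no nonzero codon weight")
        weights = {c: w / top for c, w in absolute.items()}
        nonzero = [w for w in weights.values() if w > 0]
        gm = math.exp(sum(math.log(w) for w in nonzero) / len(nonzero))
        return {c: (w if w > 0 else gm) for c, w in weights.items()}

    @classmethod
    def default_tgcn(cls) -> dict[str, float]:
        """Bundled S. cerevisiae tRNA gene copy numbers by anticodon."""
        from importlib.resources import files

        path = files("translatomics").joinpath("data/tgcn_scerevisiae.tsv")
        df = pd.read_csv(path, sep="\t", comment="#")
        return dict(zip(df["anticodon"], df["gene_copy_number"].astype(float)))


def _geometric_mean(values: Sequence[float]) -> float:
    if not values:
        return float("nan")
    return math.exp(sum(math.log(v) for v in values) / len(values))


def cai(orf: str, weights: CodonWeightTable) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness over
    the ORF's codons, excluding single-codon families (AUG, UGG) and the
    stop codon; codons containing N are skipped."""
    ws = []
    for codon in codons_of(orf):
        if codon in STOP_CODONS or codon in _SINGLE_FAMILY:
            continue
        w = weights.cai_weights.get(codon)
        if w is None:
            logger.debug("cai: skipping codon %r", codon)
            continue
        ws.append(max(w, 1e-9))
    return _geometric_mean(ws)


def fop(orf: str, weights: CodonWeightTable) -> float:
    """Frequency of optimal codons among codons with a synonymous choice."""
    optimal = weights.optimal_codons
    n_opt = n_choice = 0
    for codon in codons_of(orf):
        if codon in STOP_CODONS or codon not in _FAMILY_OF:
            continue
        if len(FAMILIES[_FAMILY_OF[codon]]) < 2:
            continue
        n_choice += 1
        if codon in optimal:
            n_opt += 1
    return n_opt / n_choice if n_choice else float("nan")


def tai(orf: str, weights: CodonWeightTable) -> float:
    """tRNA adaptation index: geometric mean of per-codon tAI weights
    over the ORF (stop codon excluded, N-containing codons skipped)."""
    ws = []
    for codon in codons_of(orf):
        if codon in STOP_CODONS:
            continue
        w = weights.tai_weights.get(codon)
        if w is None:
            continue
        ws.append(max(w, 1e-9))
    return _geometric_mean(ws)


# ---------------------------------------------------------------------------
# Composition and start-context features
# ---------------------------------------------------------------------------


def composition_features(rec: TranscriptRecord) -> dict[str, float]:
    """Region lengths (3) and per-region base fractions (12).

    N bases are excluded from fraction denominators; an empty region has
    length 0 and all fractions 0.
    """
    out: dict[str, float] = {}
    for region in ("utr5", "orf", "utr3"):
        seq = getattr(rec, region)
        out[f"{region}_len"] = float(len(seq))
        denom = len(seq) - seq.count("N")
        for base in "ACGU":
            out[f"{region}_frac_{base}"] = (
                seq.count(base) / denom if denom else 0.0
            )
    return out


def aa_composition(orf: str, skip_n: bool = True) -> dict[str, float]:
    """Amino-acid composition of the encoded protein (20 fractions summing
    to 1; terminal stop excluded).  An internal stop raises ValueError."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    codons = codons_of(orf)
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    total = 0
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {i}")
        aa = _CODE.forward_table.get(codon)
        if aa is None:
            if skip_n and "N" in codon:
                continue
            raise ValueError(f"untranslatable codon {codon!r}")
        counts[aa] += 1
        total += 1
    return {
        f"aa_frac_{aa}": (counts[aa] / total if total else 0.0)
        for aa in AMINO_ACIDS
    }


@dataclass
class StartContextTable:
    """Positional base frequencies at -6..-1 upstream of the start AUG,
    learned from a reference transcript set; used for AUG-CAI(r)."""

    freqs: np.ndarray  # 4 x 6, rows A,C,G,U; columns -6..-1

    WIDTH = 6
    _ROW = {"A": 0, "C": 1, "G": 2, "U": 3}

    @classmethod
    def from_records(cls, records: Iterable[TranscriptRecord]) -> "StartContextTable":
        counts = np.full((4, cls.WIDTH), 0.5)
        for rec in records:
            ctx = rec.utr5[-cls.WIDTH:]
            offset = cls.WIDTH - len(ctx)
            for j, base in enumerate(ctx):
                if base in cls._ROW:
                    counts[cls._ROW[base], offset + j] += 1
        return cls(counts / counts.sum(axis=0, keepdims=True))

    def score(self, rec: TranscriptRecord) -> float:
        """Geometric mean over available context positions of
        f(base)/f_max; NaN when the 5'UTR is empty."""
        ctx = rec.utr5[-self.WIDTH:]
        if not ctx:
            return float("nan")
        offset = self.WIDTH - len(ctx)
        fmax = self.freqs.max(axis=0)
        ratios = []
        for j, base in enumerate(ctx):
            if base not in self._ROW:
                continue
            col = offset + j
            ratios.append(self.freqs[self._ROW[base], col] / fmax[col])
        if not ratios:
            return float("nan")
        return _geometric_mean([max(r, 1e-9) for r in ratios])


def _gc_fraction(seq: str) -> float:
    denom = len(seq) - seq.count("N")
    if not denom:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / denom


def start_context_features(
    rec: TranscriptRecord,
    context_table: StartContextTable | None = None,
    gc_window: int = 30,
) -> dict[str, float]:
    """Start-codon context block: AUG-CAI(r), GC before/after the start,
    upstream AUG count, uORF presence and 5'UTR stop presence.

    Windows shorter than ``gc_window`` are truncated at region boundaries.
    The uORF flag requires an upstream AUG with an in-frame stop wholly
    inside the 5'UTR.
    """
    utr5 = rec.utr5
    out: dict[str, float] = {}
    out["aug_cai_r"] = (
        context_table.score(rec) if context_table is not None else float("nan")
    )
    out["gc_before_start"] = _gc_fraction(utr5[-gc_window:]) if utr5 else float("nan")
    out["gc_after_start"] = _gc_fraction(rec.orf[3: 3 + gc_window])

    uaugs = [m.start() for m in re.finditer("(?=AUG)", utr5)]
    out["uaug_count"] = float(len(uaugs))
    uorf = 0.0
    for start in uaugs:
        for j in range(start + 3, len(utr5) - 2, 3):
            if utr5[j: j + 3] in STOP_CODONS:
                uorf = 1.0
                break
        if uorf:
            break
    out["uorf_present"] = uorf
    out["utr5_stop_present"] = float(
        any(s in utr5 for s in STOP_CODONS)
    )
    return out


# ---------------------------------------------------------------------------
# Motif scanning and folding
# ---------------------------------------------------------------------------


def _consensus_regex(consensus: str) -> re.Pattern:
    parts = []
    for code in consensus:
        options = "".join(sorted(IUPAC_RNA[code]))
        if code == "N":
            options += "N"  # sequence N matches only fully degenerate positions
        parts.append(f"[{options}]" if len(options) > 1 else options)
    return re.compile(f"(?={''.join(parts)})")


def scan_motif(seq: str, motif: MotifModel) -> float:
    """Score one motif against one sequence (forward strand only).

    ``count`` scoring returns the number of (possibly overlapping) windows
    matching the IUPAC consensus; ``max_log_odds`` returns the maximum over
    windows of sum log2(PWM(base, i) / 0.25).  Sequences shorter than the
    motif yield 0 (count) or the documented floor (max_log_odds).
    """
    L = len(motif)
    if motif.scoring == "count":
        if motif.consensus is None:
            raise ValueError(
                f"motif {motif.name!r}: count scoring requires a consensus"
            )
        if len(seq) < L:
            return 0.0
        return float(len(_consensus_regex(motif.consensus).findall(seq)))
    # max_log_odds
    if len(seq) < L:
        return MOTIF_LOG_ODDS_FLOOR
    if motif.pwm is None:
        raise ValueError("max_log_odds scoring requires a PWM")
    logodds = np.log2(np.maximum(motif.pwm, 1e-6) / 0.25)
    row = {"A": 0, "C": 1, "G": 2, "U": 3}
    best = MOTIF_LOG_ODDS_FLOOR
    for i in range(len(seq) - L + 1):
        window = seq[i: i + L]
        if "N" in window:
            continue
        score = sum(logodds[row[b], j] for j, b in enumerate(window))
        best = max(best, score)
    return float(best)


def fold_energy(
    seq: str,
    engine: str = "internal_proxy",
    max_window: int | None = 70,
    pair_bonus: float = 1.0,
    stack_bonus: float = 1.0,
    external_command: Sequence[str] | None = None,
) -> float:
    """Structural pseudo-energy of a region (lower = more structured).

    The default internal proxy is a deterministic maximum base-pairing
    dynamic program with stacking bonuses (see :mod:`translatomics._fold`);
    only the first ``max_window`` nt are folded.  ``engine='external'``
    pipes the sequence to a thermodynamic folder command (e.g. RNAfold)
    and parses the trailing ``(... dG)`` energy.  Regions shorter than
    8 nt score 0.
    """
    if engine == "internal_proxy":
        return pairing_pseudo_energy(
            seq, pair_bonus=pair_bonus, stack_bonus=stack_bonus,
            max_window=max_window,
        )
    if engine == "external":
        import subprocess

        if not external_command:
            raise ValueError("external engine requires external_command")
        if len(seq) < 8:
            return 0.0
        proc = subprocess.run(
            list(external_command), input=seq + "\n", capture_output=True,
            text=True, check=True,
        )
        match = re.search(r"\(\s*(-?\d+\.?\d*)\)\s*$", proc.stdout.strip())
        if not match:
            raise RuntimeError("could not parse external folder output")
        return float(match.group(1))
    raise ValueError(f"unknown folding engine {engine!r}")


# ---------------------------------------------------------------------------
# Feature schema and matrix
# ---------------------------------------------------------------------------


@dataclass
class FeatureSchema:
    """Ordered, named feature list; the default totals exactly 77."""

    names: tuple[str, ...]
    version: str = "default-77"

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)


def default_schema(panel: Sequence[MotifModel] | None = None) -> FeatureSchema:
    """The default 77-feature schema.

    Blocks: region lengths (3) + base composition (12) + GC before/after
    start (2) + fold energy per region (3) + CAI/fop/tAI/AUG-CAI(r) (4) +
    amino-acid composition (20) + uAUG count, uORF presence, 5'UTR stop
    presence (3) + transcript level control/stress (2) + motif panel (28).
    """
    if panel is None:
        panel = default_motif_panel()
    names: list[str] = []
    names += ["utr5_len", "orf_len", "utr3_len"]
    names += [
        f"{region}_frac_{b}" for region in ("utr5", "orf", "utr3") for b in "ACGU"
    ]
    names += ["gc_before_start", "gc_after_start"]
    names += ["utr5_fold_energy", "orf_fold_energy", "utr3_fold_energy"]
    names += ["cai", "fop", "tai", "aug_cai_r"]
    names += [f"aa_frac_{aa}" for aa in AMINO_ACIDS]
    names += ["uaug_count", "uorf_present", "utr5_stop_present"]
    names += ["transcript_level_control", "transcript_level_stress"]
    names += [m.name for m in panel]
    return FeatureSchema(tuple(names))


class SequenceFeaturizer(BaseEstimator, TransformerMixin):
    """Build the per-mRNA feature matrix from assembled transcripts.

    ``fit`` learns the data-derived reference tables: CAI relative
    adaptiveness and the start-context frequency table from a reference
    transcript set (by default the top decile of transcripts ranked by
    control-condition total-fraction level, or all transcripts when no
    expression is given), plus the bundled tAI weight table.  ``transform``
    emits one row per transcript in schema order, with per-feature median
    imputation of missing values (empty UTRs, absent expression).

    Parameters
    ----------
    panel : list of MotifModel or None
        Motif panel; None loads the bundled 28-entry panel.
    gc_window : int
        Window (nt) for GC content before/after the start codon.
    fold_max_window : int or None
        Fold only the first this-many nt of each region (the DP is cubic).
    cai_reference : "top_decile" | "all" | list of transcript ids
        Reference set for CAI weights and the start-context table.
    """

    def __init__(
        self,
        panel: Sequence[MotifModel] | None = None,
        gc_window: int = 30,
        fold_engine: str = "internal_proxy",
        fold_max_window: int | None = 70,
        fold_pair_bonus: float = 1.0,
        fold_stack_bonus: float = 1.0,
        cai_reference: str | Sequence[str] = "top_decile",
        impute: str = "median",
    ):
        self.panel = panel
        self.gc_window = gc_window
        self.fold_engine = fold_engine
        self.fold_max_window = fold_max_window
        self.fold_pair_bonus = fold_pair_bonus
        self.fold_stack_bonus = fold_stack_bonus
        self.cai_reference = cai_reference
        self.impute = impute

    # -- fitting -------------------------------------------------------
    def _reference_records(
        self, records: Sequence[TranscriptRecord], expression
    ) -> Sequence[TranscriptRecord]:
        if isinstance(self.cai_reference, str):
            if self.cai_reference == "all" or expression is None:
                return records
            if self.cai_reference != "top_decile":
                raise ValueError(f"unknown cai_reference {self.cai_reference!r}")
            if not expression.has_fraction("total"):
                return records
            level = expression.cell_mean("control", "total")
            level = level.reindex([r.id for r in records]).dropna()
            if level.empty:
                return records
            n_ref = max(10, int(round(len(level) / 10)))
            top = set(level.sort_values(ascending=False).index[:n_ref])
            return [r for r in records if r.id in top] or records
        chosen = set(self.cai_reference)
        return [r for r in records if r.id in chosen] or records

    def fit(self, X: Sequence[TranscriptRecord], y=None, expression=None):
        if not X:
            raise ValueError("no transcripts to fit on")
        self.panel_ = list(self.panel) if self.panel is not None else default_motif_panel()
        self.schema_ = default_schema(self.panel_)
        ref = self._reference_records(X, expression)
        self.reference_ids_ = tuple(r.id for r in ref)
        self.weights_ = CodonWeightTable(
            cai_weights=CodonWeightTable.cai_from_reference(r.orf for r in ref),
            tai_weights=CodonWeightTable.tai_from_tgcn(
                CodonWeightTable.default_tgcn()
            ),
        )
        self.context_table_ = StartContextTable.from_records(ref)
        self.feature_names_ = list(self.schema_.names)
        return self

    # -- transform -----------------------------------------------------
    def _transcript_row(self, rec: TranscriptRecord) -> dict[str, float]:
        row = composition_features(rec)
        row.update(
            start_context_features(
                rec, context_table=self.context_table_, gc_window=self.gc_window
            )
        )
        for region in ("utr5", "orf", "utr3"):
            row[f"{region}_fold_energy"] = fold_energy(
                getattr(rec, region),
                engine=self.fold_engine,
                max_window=self.fold_max_window,
                pair_bonus=self.fold_pair_bonus,
                stack_bonus=self.fold_stack_bonus,
            )
        row["cai"] = cai(rec.orf, self.weights_)
        row["fop"] = fop(rec.orf, self.weights_)
        row["tai"] = tai(rec.orf, self.weights_)
        row.update(aa_composition(rec.orf))
        for motif in self.panel_:
            region = motif.target_region
            seq = rec.sequence if region == "any" else getattr(rec, region)
            row[motif.name] = scan_motif(seq, motif)
        return row

    def transform(
        self, X: Sequence[TranscriptRecord], expression=None
    ) -> pd.DataFrame:
        if not hasattr(self, "schema_"):
            raise ValueError("featurizer is not fitted")
        rows = {rec.id: self._transcript_row(rec) for rec in X}
        df = pd.DataFrame.from_dict(rows, orient="index")
        # transcript-level expression features
        for cond in ("control", "stress"):
            col = f"transcript_level_{cond}"
            if expression is not None and expression.has_fraction("total"):
                df[col] = expression.cell_mean(cond, "total").reindex(df.index)
            else:
                df[col] = np.nan
        missing_schema = [n for n in self.schema_.names if n not in df.columns]
        if missing_schema:
            raise ValueError(
                f"schema references features absent from the panel: {missing_schema}"
            )
        df = df[list(self.schema_.names)]
        df.index.name = "gene"
        self.missing_mask_ = df.isna()
        if self.impute == "median":
            med = df.median(numeric_only=True)
            df = df.fillna(med.fillna(0.0))
        return df

    def fit_transform(self, X, y=None, expression=None) -> pd.DataFrame:
        return self.fit(X, expression=expression).transform(X, expression=expression)


def build_feature_matrix(
    records: Sequence[TranscriptRecord],
    expression=None,
    panel: Sequence[MotifModel] | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, SequenceFeaturizer]:
    """One-call feature matrix under the default schema."""
    featurizer = SequenceFeaturizer(panel=panel, **kwargs)
    matrix = featurizer.fit_transform(records, expression=expression)
    return matrix, featurizer
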