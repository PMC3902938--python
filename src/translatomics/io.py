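"""Readers and writers for the external formats the pipeline touches.

All sequence data is normalised to the RNA alphabet (``U``) on read; DNA
input (``T``) is accepted and converted.  Every reader validates its input
and raises :class:`FormatError` with a located message rather than coercing
silently.  Writers emit plain TSV / FASTA / GMT so that ``read(write(x))``
round-trips exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGUN")

#: IUPAC nucleotide codes in RNA space.
IUPAC_RNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

MOTIF_REGIONS = ("utr5", "orf", "utr3", "any")
MOTIF_SCORINGS = ("count", "max_log_odds")


class FormatError(ValueError):
    """Malformed input in one of the supported on-disk formats."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T->U (the internal alphabet is RNA)."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class SequenceRecord:
    """One transcript sequence in RNA space."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if len(self.sequence) < 1:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            pos = next(
                i for i, b in enumerate(self.sequence) if b in bad
            )
            raise FormatError(
                f"non-IUPAC character {self.sequence[pos]!r} at position {pos} "
                f"in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read transcript sequences from FASTA, normalising T->U.

    Raises :class:`FormatError` on duplicate ids, empty sequences, or
    characters outside {A,C,G,T,U,N}.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, normalize_rna(str(rec.seq))))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Region table
# ---------------------------------------------------------------------------

REGION_COLUMNS = ["transcript_id", "utr5_len", "orf_len", "utr3_len"]


@dataclass
class RegionTable:
    """Per-transcript 5'UTR / ORF / 3'UTR lengths (transcript-local nt).

    ``table`` is indexed by transcript id with integer columns ``utr5_len``,
    ``orf_len``, ``utr3_len``.  ``n_excluded`` counts input rows dropped for
    violating the region invariants (undefined UTRs when required, ORF not a
    multiple of three, negative lengths).
    """

    table: pd.DataFrame
    n_excluded: int = 0
    excluded_ids: list[str] = field(default_factory=list)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def lengths(self, transcript_id: str) -> tuple[int, int, int]:
        row = self.table.loc[transcript_id]
        return int(row["utr5_len"]), int(row["orf_len"]), int(row["utr3_len"])


def read_region_table(
    path: str | Path, require_utrs: bool = True
) -> RegionTable:
    """Read a tab-delimited UTR/ORF length table.

    Rows violating the invariants (negative lengths; ORF shorter than one
    codon or not divisible by 3; zero-length UTR when ``require_utrs``) are
    dropped with a warning, mirroring the exclusion of transcripts without
    experimentally defined UTRs; the exclusion count is reported on the
    returned :class:`RegionTable`.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"region table {path} missing columns {missing}")
    dup = df["transcript_id"][df["transcript_id"].duplicated()]
    if len(dup):
        raise FormatError(
            f"duplicate transcript_id {dup.iloc[0]!r} in region table {path}"
        )
    keep = np.ones(len(df), dtype=bool)
    for col in ("utr5_len", "orf_len", "utr3_len"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        keep &= ~bad.to_numpy()
        df[col] = vals
    orf = df["orf_len"]
    keep &= (orf >= 3).to_numpy() & (orf % 3 == 0).to_numpy()
    if require_utrs:
        keep &= (df["utr5_len"] > 0).to_numpy() & (df["utr3_len"] > 0).to_numpy()
    excluded = df.loc[~keep, "transcript_id"].astype(str).tolist()
    if excluded:
        logger.warning(
            "region table: excluded %d transcript(s) violating region "
            "invariants: %s%s",
            len(excluded),
            ", ".join(excluded[:5]),
            "..." if len(excluded) > 5 else "",
        )
    out = df.loc[keep, REGION_COLUMNS].copy()
    out[["utr5_len", "orf_len", "utr3_len"]] = out[
        ["utr5_len", "orf_len", "utr3_len"]
    ].astype(int)
    out = out.set_index("transcript_id")
    out.index = out.index.astype(str)
    return RegionTable(out, n_excluded=len(excluded), excluded_ids=excluded)


def write_region_table(regions: RegionTable, path: str | Path) -> None:
    regions.table.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression table
# ---------------------------------------------------------------------------

EXPRESSION_COLUMNS = ["gene", "condition", "fraction", "replicate", "log2_intensity"]
CONDITIONS = ("control", "stress")
FRACTIONS = ("total", "monosome", "polysome")


def read_expression_table(path: str | Path):
    """Read a long-format log2-intensity table into an ExpressionMatrix.

    Columns: gene, condition in {control, stress}, fraction in
    {total, monosome, polysome}, replicate (int), log2_intensity (float).
    """
    from .expression import ExpressionMatrix

    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"expression table {path} missing columns {missing}")
    vals = pd.to_numeric(df["log2_intensity"], errors="coerce")
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise FormatError(
            f"non-numeric log2_intensity at data row {row} of {path}"
        )
    df["log2_intensity"] = vals
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise FormatError(f"unknown condition(s) {sorted(bad_cond)} in {path}")
    bad_frac = set(df["fraction"]) - set(FRACTIONS)
    if bad_frac:
        raise FormatError(f"unknown fraction(s) {sorted(bad_frac)} in {path}")
    key = ["gene", "condition", "fraction", "replicate"]
    dups = df.duplicated(subset=key)
    if dups.any():
        first = df.loc[dups, key].iloc[0].tolist()
        raise FormatError(f"duplicate observation {first} in {path}")
    return ExpressionMatrix.from_long(df)


def write_expression_table(matrix, path: str | Path, header: str | None = None) -> None:
    long = matrix.to_long()
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        long.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Motif panel
# ---------------------------------------------------------------------------


@dataclass
class MotifModel:
    """An RNA-binding-protein binding-site model.

    Either an IUPAC consensus string or a 4 x L position weight matrix
    (rows A, C, G, U; columns sum to 1).  ``target_region`` restricts
    scanning to one transcript region; ``scoring`` selects occurrence
    counting or max log-odds over windows.
    """

    name: str
    consensus: str | None = None
    pwm: np.ndarray | None = None
    target_region: str = "any"
    scoring: str = "count"

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.pwm is None):
            raise FormatError(
                f"motif {self.name!r}: exactly one of consensus/PWM required"
            )
        if self.target_region not in MOTIF_REGIONS:
            raise FormatError(
                f"motif {self.name!r}: unknown target_region {self.target_region!r}"
            )
        if self.scoring not in MOTIF_SCORINGS:
            raise FormatError(
                f"motif {self.name!r}: unknown scoring {self.scoring!r}"
            )
        if self.consensus is not None:
            self.consensus = normalize_rna(self.consensus)
            bad = set(self.consensus) - set(IUPAC_RNA)
            if bad:
                raise FormatError(
                    f"motif {self.name!r}: non-IUPAC code(s) {sorted(bad)}"
                )
            if len(self.consensus) < 4:
                raise FormatError(f"motif {self.name!r}: length < 4")
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape[0] != 4 or self.pwm.shape[1] < 4:
                raise FormatError(
                    f"motif {self.name!r}: PWM must be 4 x L with L >= 4"
                )
            sums = self.pwm.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise FormatError(
                    f"motif {self.name!r}: PWM columns must sum to 1 "
                    f"(got {sums.round(6).tolist()})"
                )

    def __len__(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[1]


def read_motif_panel(path: str | Path) -> list[MotifModel]:
    """Read a TSV motif panel: name, consensus_or_pwm, target_region, scoring.

    A ``consensus_or_pwm`` entry starting with ``@`` names a sidecar TSV
    (relative to the panel file) holding a 4-row PWM (rows A,C,G,U).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = ["name", "consensus_or_pwm", "target_region", "scoring"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"motif panel {path} missing columns {missing}")
    motifs: list[MotifModel] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        name = str(row["name"])
        if name in seen:
            raise FormatError(f"duplicate motif name {name!r} in {path}")
        seen.add(name)
        ref = str(row["consensus_or_pwm"])
        if ref.startswith("@"):
            pwm = np.loadtxt(path.parent / ref[1:], delimiter="\t")
            motifs.append(
                MotifModel(name, pwm=pwm, target_region=row["target_region"],
                           scoring=row["scoring"])
            )
        else:
            motifs.append(
                MotifModel(name, consensus=ref, target_region=row["target_region"],
                           scoring=row["scoring"])
            )
    return motifs


def default_motif_panel() -> list[MotifModel]:
    """The bundled RBP motif panel (28 motif x region scores)."""
    from importlib.resources import files

    return read_motif_panel(files("translatomics").joinpath("data/motif_panel.tsv"))


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets over an optional declared universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is not None:
            for name, members in list(self.sets.items()):
                stray = members - self.universe
                if stray:
                    logger.warning(
                        "gene set %r: dropping %d member(s) outside the "
                        "declared universe", name, len(stray)
                    )
                    self.sets[name] = members - stray

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def effective_universe(self) -> frozenset[str]:
        if self.universe is not None:
            return self.universe
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


def read_gene_sets(
    path: str | Path, universe: Iterable[str] | None = None
) -> GeneSetCollection:
    """Read a GMT file (name, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: not a GMT line")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(p for p in parts[2:] if p)
            if not members:
                logger.warning("%s:%d: empty gene set %r dropped", path, lineno, name)
                continue
            sets[name] = members
    return GeneSetCollection(
        sets, frozenset(universe) if universe is not None else None
    )


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")
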