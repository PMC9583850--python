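"""Design-vs-results gRNA verification from raw sequencing reads.

Circuit builds are checked by exact substring search: a gRNA is "present"
in a strain when at least one raw read contains the gRNA sequence or its
reverse complement.  The observed presence/absence matrix is compared
against the design matrix derived from each strain's part list; cells
that disagree are anomalies — unexpected absences (possible build errors
or coverage gaps) or unexpected presences (possible mislabeling, design
errors or contamination).  Matching operates on raw reads, so a coding
sequence cannot be distinguished from its identically-sequenced promoter
target site; the design matrix ORs the two roles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .circuit_model import StrainSpec

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

EXPECTED = "expected"
UNEXPECTED_ABSENCE = "unexpected_absence"  # design 1, results 0 (orange)
UNEXPECTED_PRESENCE = "unexpected_presence"  # design 0, results 1 (blue)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GRNALibrary:
    """Named gRNA DNA sequences (~20 nt, strict A/C/G/T)."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.entries.items():
            if not seq:
                raise ValueError(f"gRNA {name!r} has an empty sequence")
            if not set(seq.upper()) <= _VALID:
                raise ValueError(f"gRNA {name!r} has non-ACGT characters")

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> str:
        return self.entries[name]

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GRNALibrary":
        from Bio import SeqIO

        return cls(
            {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GRNALibrary":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["name"], df["sequence"].str.upper())))

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.entries.items():
                fh.write(f">{name}\n{seq}\n")


def search_grna(
    reads: Iterable[str], grna: str, min_hits: int = 1
) -> int:
    """1 iff >= ``min_hits`` reads contain the gRNA or its reverse complement.

    Exact matching only: reads with ambiguous bases (e.g. N) can never
    match at those positions.  Non-ACGT characters in the gRNA itself
    are an error.
    """
    grna = grna.upper()
    if not set(grna) <= _VALID:
        raise ValueError("gRNA sequence must contain only A/C/G/T")
    rc = reverse_complement(grna)
    hits = 0
    for read in reads:
        r = read.upper()
        if grna in r or rc in r:
            hits += 1
            if hits >= min_hits:
                return 1
    return 0


@dataclass
class PresenceMatrix:
    """Strain x gRNA 0/1 indicator matrix (design or results role).

    ``missing_rows`` records strains with no read data at all — flagged
    rather than zero-filled, since absence of evidence is not evidence
    of absence.
    """

    table: pd.DataFrame  # index: strain labels, columns: gRNA names, values 0/1
    role: str  # "design" or "results"
    missing_rows: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = self.table.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence matrix cells must be 0 or 1")


def build_results_matrix(
    reads_by_strain: Mapping[str, Sequence[str]],
    library: GRNALibrary,
    min_hits: int = 1,
) -> PresenceMatrix:
    """Observed presence matrix from exact-match read search.

    Strains whose read set is empty are listed in ``missing_rows`` and
    excluded from the table.
    """
    missing = tuple(s for s, reads in reads_by_strain.items() if len(reads) == 0)
    rows = {}
    for strain, reads in reads_by_strain.items():
        if strain in missing:
            continue
        rows[strain] = [search_grna(reads, library[g], min_hits) for g in library]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=library.names, dtype=int
    )
    return PresenceMatrix(table, role="results", missing_rows=missing)


def build_design_matrix(
    strains: Sequence[StrainSpec], library: GRNALibrary
) -> PresenceMatrix:
    """Expected presence matrix from the strains' gRNA part lists.

    A cell is 1 iff the strain's design carries the gRNA as a coding
    sequence or target site (the part list does not distinguish them).
    A part named in a design but absent from the library is an error.
    """
    names = set(library.names)
    for s in strains:
        unknown = set(s.grnas) - names
        if unknown:
            raise KeyError(
                f"strain {s.label} designs use gRNAs missing from library: "
                f"{sorted(unknown)}"
            )
    table = pd.DataFrame(
        [[int(g in s.grnas) for g in library] for s in strains],
        index=[s.label for s in strains],
        columns=library.names,
        dtype=int,
    )
    return PresenceMatrix(table, role="design")


@dataclass
class AnomalyMatrix:
    """Cell-wise design/results disagreement classification."""

    table: pd.DataFrame  # values in {expected, unexpected_absence, unexpected_presence}

    @property
    def n_anomalies(self) -> int:
        return int((self.table.to_numpy() != EXPECTED).sum())

    def counts_by_strain(self) -> pd.DataFrame:
        t = self.table
        return pd.DataFrame(
            {
                "unexpected_absence": (t == UNEXPECTED_ABSENCE).sum(axis=1),
                "unexpected_presence": (t == UNEXPECTED_PRESENCE).sum(axis=1),
            }
        )

    def counts_by_grna(self) -> pd.DataFrame:
        t = self.table
        return pd.DataFrame(
            {
                "unexpected_absence": (t == UNEXPECTED_ABSENCE).sum(axis=0),
                "unexpected_presence": (t == UNEXPECTED_PRESENCE).sum(axis=0),
            }
        )


def find_anomalies(design: PresenceMatrix, results: PresenceMatrix) -> AnomalyMatrix:
    """Classify every cell where results disagree with design.

    Rows are intersected on strains present in both matrices (strains
    without read data cannot be classified); columns must match exactly.
    """
    if list(design.table.columns) != list(results.table.columns):
        raise ValueError("design and results matrices have different gRNA columns")
    common = [s for s in design.table.index if s in results.table.index]
    d = design.table.loc[common]
    r = results.table.loc[common]
    cls = pd.DataFrame(EXPECTED, index=d.index, columns=d.columns)
    cls = cls.mask((d == 1) & (r == 0), UNEXPECTED_ABSENCE)
    cls = cls.mask((d == 0) & (r == 1), UNEXPECTED_PRESENCE)
    return AnomalyMatrix(cls)


def design_compatibility(
    observed_row: Mapping[str, int],
    candidate_designs: Sequence[StrainSpec],
    strict: bool = False,
) -> list[StrainSpec]:
    """Candidate designs compatible with an observed presence row.

    A candidate is compatible iff every gRNA its design requires was
    observed present.  With ``strict=True``, observed gRNAs that the
    design does not require also rule it out (exact set match).
    """
    present = {g for g, v in observed_row.items() if v == 1}
    compatible = []
    for cand in candidate_designs:
        required = set(cand.grnas)
        if not required <= present:
            continue
        if strict and present - required:
            continue
        compatible.append(cand)
    return compatible


def coverage_estimate(
    reads_by_strain: Mapping[str, Sequence[str]], genome_size: int
) -> pd.Series:
    """Fold sequencing coverage per strain: total read bases / genome size."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    return pd.Series(
        {s: sum(len(r) for r in reads) / genome_size for s, reads in reads_by_strain.items()},
        name="coverage",
    )


def read_fasta_reads(path: str | Path) -> list[str]:
    """Load raw reads from a FASTA/FASTQ file (gzip-transparent)."""
    import gzip

    from Bio import SeqIO

    p = Path(path)
    fmt = "fastq" if ".fastq" in p.suffixes or ".fq" in p.suffixes else "fasta"
    opener = gzip.open if p.suffix == ".gz" else open
    with opener(p, "rt") as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)]
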