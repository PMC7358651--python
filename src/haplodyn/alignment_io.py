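"""Alignment handling: reading, concatenation, indel coding, haplotype collapse.

Chloroplast regions are sequenced separately, aligned upstream, concatenated
into one matrix, and insertion/deletion events are recoded as single binary
characters so that a multi-column gap counts as one evolutionary event.
Identical coded sequences are then collapsed into haplotypes, the unit every
downstream population-genetic computation consumes.

Conventions: positions are 0-based and intervals half-open; sequence ids are
matched case-sensitively; the gap character is ``-``; columns containing ``N``
are treated as ambiguous and excluded from segregating-site and distance
computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "Alignment",
    "HaplotypeTable",
    "read_alignment",
    "read_population_table",
    "write_fasta",
    "concatenate",
    "code_indels",
    "collapse_haplotypes",
]

GAP = "-"
AMBIGUOUS = "N"
#: characters used for the presence/absence states of a coded indel event
INDEL_ABSENT, INDEL_PRESENT = "0", "1"


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment.

    ``n_indel_chars`` is the number of trailing columns that are coded
    indel characters (``0``/``1``) rather than nucleotides; it is 0 for a
    freshly read alignment and set by :func:`code_indels`.
    """

    ids: list[str]
    seqs: list[str]
    n_indel_chars: int = 0

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def matrix(self) -> np.ndarray:
        """(n, L) array of single-byte characters."""
        if not self.seqs:
            return np.empty((0, 0), dtype="S1")
        return np.frombuffer("".join(self.seqs).encode(), dtype="S1").reshape(
            self.n, self.length
        )

    def subset(self, ids: list[str]) -> "Alignment":
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"ids not in alignment: {missing[:5]}")
        return Alignment(
            ids=list(ids),
            seqs=[self.seqs[index[s]] for s in ids],
            n_indel_chars=self.n_indel_chars,
        )


@dataclass
class HaplotypeTable:
    """Distinct coded haplotypes with per-population counts.

    ``haplotypes`` maps labels (``h1`` .. ``hK``, assigned by decreasing
    total count, ties broken by first occurrence in the alignment) to coded
    sequences.  ``counts`` is a population x haplotype DataFrame whose row
    sums equal the population sample sizes.
    """

    haplotypes: dict[str, str]
    counts: pd.DataFrame
    assignments: pd.Series  # sequence id -> haplotype label
    S: int
    n_indel_chars: int

    @property
    def h(self) -> int:
        return len(self.haplotypes)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def populations(self) -> list[str]:
        return list(self.counts.index)

    def population_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def frequencies(self) -> pd.DataFrame:
        """Per-population haplotype frequencies (rows sum to 1)."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.T.copy()
        out.insert(0, "sequence", [self.haplotypes[h] for h in out.index])
        out.index.name = "haplotype"
        out.to_csv(path, sep="\t")


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read a multi-FASTA or sequential NEXUS alignment."""
    path = Path(path)
    if fmt is None:
        fmt = "nexus" if path.suffix.lower() in {".nex", ".nexus"} else "fasta"
    msa = AlignIO.read(str(path), fmt)
    return Alignment(ids=[rec.id for rec in msa], seqs=[str(rec.seq) for rec in msa])


def read_population_table(path: str | Path) -> pd.DataFrame:
    """Read the TSV mapping sequence_id -> population (plus lat/lon)."""
    table = pd.read_csv(path, sep="\t", dtype={"sequence_id": str, "population": str})
    required = {"sequence_id", "population"}
    if not required.issubset(table.columns):
        raise ValueError(f"population table must have columns {sorted(required)}")
    return table


def write_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def concatenate(alignments: list[Alignment]) -> Alignment:
    """Concatenate per-region alignments over a shared id set.

    Rows are joined region-wise in the given order; the id *sets* must be
    identical across regions (row order may differ).
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    first = alignments[0]
    ref_ids = set(first.ids)
    for aln in alignments[1:]:
        if set(aln.ids) != ref_ids:
            raise ValueError("alignments have different id sets")
        if aln.n_indel_chars:
            raise ValueError("concatenate raw alignments before indel coding")
    seqs = []
    for sid in first.ids:
        parts = []
        for aln in alignments:
            parts.append(aln.seqs[aln.ids.index(sid)])
        seqs.append("".join(parts))
    return Alignment(ids=list(first.ids), seqs=seqs)


def code_indels(aln: Alignment) -> tuple[Alignment, int]:
    """Recode insertion/deletion events as single binary characters.

    A maximal run of consecutive gap-containing columns sharing an identical
    gap presence/absence pattern across sequences is one indel event.  All
    gap-containing columns are removed from the nucleotide matrix and one
    ``0``/``1`` character per event (``1`` = sequence carries the gap) is
    appended after it.  Returns the recoded alignment and the event count.
    """
    if aln.n_indel_chars:
        raise ValueError("alignment already indel-coded")
    mat = aln.matrix()
    gap = mat == GAP.encode()
    gap_cols = np.flatnonzero(gap.any(axis=0))
    if gap.all(axis=0).any():
        raise ValueError("column is gapped in every sequence; alignment defect")
    events: list[np.ndarray] = []
    prev_col = None
    for col in gap_cols:
        pattern = gap[:, col]
        if prev_col is not None and col == prev_col + 1 and np.array_equal(
            pattern, events[-1]
        ):
            prev_col = col
            continue
        events.append(pattern.copy())
        prev_col = col
    keep = np.setdiff1d(np.arange(aln.length), gap_cols)
    core = mat[:, keep]
    rows = [b"".join(core[i]).decode() for i in range(aln.n)]
    for pattern in events:
        for i in range(aln.n):
            rows[i] += INDEL_PRESENT if pattern[i] else INDEL_ABSENT
    return (
        Alignment(ids=list(aln.ids), seqs=rows, n_indel_chars=len(events)),
        len(events),
    )


def segregating_sites(aln: Alignment) -> int:
    """Polymorphic nucleotide columns, excluding gapped/ambiguous columns
    and coded indel characters."""
    mat = aln.matrix()
    L_nuc = aln.length - aln.n_indel_chars
    mat = mat[:, :L_nuc]
    bad = (mat == GAP.encode()) | (mat == AMBIGUOUS.encode())
    usable = ~bad.any(axis=0)
    varying = (mat != mat[0]).any(axis=0)
    return int((usable & varying).sum())


def collapse_haplotypes(
    aln: Alignment,
    populations: pd.DataFrame | dict[str, str],
    use_indels: bool = True,
) -> HaplotypeTable:
    """Collapse identical coded sequences into a haplotype table.

    With ``use_indels=False`` the trailing coded indel characters are
    ignored before comparing sequences, reproducing the "haplotypes without
    indels" count.  Every id must be assigned to exactly one population and
    no population may be empty.
    """
    if isinstance(populations, pd.DataFrame):
        pop_of = dict(zip(populations["sequence_id"], populations["population"]))
    else:
        pop_of = dict(populations)
    unassigned = [sid for sid in aln.ids if sid not in pop_of]
    if unassigned:
        raise ValueError(f"ids without population assignment: {unassigned[:5]}")

    n_indel = aln.n_indel_chars
    if use_indels:
        keyed = aln.seqs
    else:
        keyed = [s[: len(s) - n_indel] if n_indel else s for s in aln.seqs]

    first_seen: dict[str, int] = {}
    members: dict[str, list[int]] = {}
    for i, key in enumerate(keyed):
        if key not in first_seen:
            first_seen[key] = i
            members[key] = []
        members[key].append(i)

    order = sorted(first_seen, key=lambda k: (-len(members[k]), first_seen[k]))
    labels = {key: f"h{rank + 1}" for rank, key in enumerate(order)}

    pop_order = list(dict.fromkeys(pop_of[sid] for sid in aln.ids))
    counts = pd.DataFrame(
        0, index=pop_order, columns=[labels[k] for k in order], dtype=int
    )
    assignment = {}
    for key, idxs in members.items():
        for i in idxs:
            sid = aln.ids[i]
            counts.loc[pop_of[sid], labels[key]] += 1
            assignment[sid] = labels[key]
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("empty population in table")

    return HaplotypeTable(
        haplotypes={labels[k]: k for k in order},
        counts=counts,
        assignments=pd.Series(assignment, name="haplotype"),
        S=segregating_sites(aln),
        n_indel_chars=0 if not use_indels else n_indel,
    )
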