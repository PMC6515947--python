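"""Sequence reconstruction and overlapping-peptide (pepscan) tiling.

The antigen studied here is beta-2 glycoprotein I (β2GP1), a 326-residue,
five-domain plasma protein. Its mature sequence is reconstructed by
stitching the overlapping 15-mer peptides of the packaged array table rather
than shipped as a FASTA, which avoids any ambiguity about the signal-peptide
offset of database entries. All residue coordinates are 1-based inclusive.

A pepscan tiling steps a fixed-length window along the protein. With the
default window of 15 and step of 4, consecutive peptides overlap by 11
residues, so any linear epitope of up to 11 residues is contained intact in
at least one peptide. When the last regular window would overrun the
C-terminus, a single final window anchored to the last residue is emitted
instead, so the terminal residues are still covered by a full-length peptide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    CoverageGap,
    EmptyMotif,
    InconsistentLabels,
    OverlapConflict,
    SequenceTooShort,
    UnmappedSpan,
)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Last residue of each sushi domain of mature β2GP1 (D1..D5). Each value is
#: drawn from the feasible set implied by the array table's domain labels
#: (D1/D2 ∈ {61,62}, D2/D3 ∈ {119,120}, D3/D4 ∈ {183,184}, D4/D5 ∈ {243,244});
#: any member reproduces the table.
DEFAULT_DOMAIN_ENDS: tuple[int, ...] = (61, 120, 183, 243, 326)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with 1-based residue indexing."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def subseq(self, start: int, end: int) -> str:
        """Substring at 1-based inclusive span [start, end]."""
        if not (1 <= start <= end <= len(self.residues)):
            raise IndexError(f"span {start}-{end} outside 1-{len(self.residues)}")
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class Peptide:
    """One tiled peptide: array index, inclusive residue span, sequence.

    ``domain_label`` is ``""`` until assigned by :func:`annotate_domains`;
    single-domain peptides get ``"k"``, boundary-spanning ones ``"k-k+1"``.
    """

    index: int
    start: int
    end: int
    sequence: str
    domain_label: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"peptide {self.index}: span {self.start}-{self.end} "
                f"inconsistent with sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TilingConfig:
    """Window geometry of the pepscan tiling."""

    window_len: int = 15
    step: int = 4
    anchor_final: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.step <= self.window_len):
            raise ValueError("require 1 <= step <= window_len")

    @property
    def overlap(self) -> int:
        return self.window_len - self.step


@dataclass(frozen=True)
class DomainMap:
    """Ordered last-residue indices of the protein's domains."""

    domain_ends: tuple[int, ...] = DEFAULT_DOMAIN_ENDS

    def __post_init__(self) -> None:
        ends = self.domain_ends
        if not ends or any(b <= a for a, b in zip(ends, ends[1:])):
            raise ValueError("domain_ends must be non-empty and strictly increasing")

    @property
    def n_domains(self) -> int:
        return len(self.domain_ends)

    def intervals(self) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) of each domain."""
        starts = (1,) + tuple(e + 1 for e in self.domain_ends[:-1])
        return list(zip(starts, self.domain_ends))


def stitch_peptides(peptides: Sequence[Peptide], seq_id: str = "stitched") -> ProteinSequence:
    """Reconstruct the unique protein sequence consistent with every peptide.

    Peptides must jointly cover ``[1, max(end)]`` and agree character-by-
    character on every overlap.

    Raises
    ------
    OverlapConflict
        If two peptides disagree at a shared residue.
    CoverageGap
        If any residue in ``[1, max(end)]`` is uncovered.
    """
    if not peptides:
        raise CoverageGap("no peptides to stitch")
    length = max(p.end for p in peptides)
    residues: list[str | None] = [None] * length
    for p in peptides:
        for offset, ch in enumerate(p.sequence):
            pos = p.start - 1 + offset
            prev = residues[pos]
            if prev is not None and prev != ch:
                raise OverlapConflict(
                    f"peptide {p.index}: residue {pos + 1} is '{ch}' "
                    f"but an earlier peptide set '{prev}'"
                )
            residues[pos] = ch
    missing = [i + 1 for i, ch in enumerate(residues) if ch is None]
    if missing:
        raise CoverageGap(f"uncovered residues: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    return ProteinSequence(id=seq_id, residues="".join(residues))  # type: ignore[arg-type]


def tile_protein(seq: ProteinSequence, cfg: TilingConfig = TilingConfig()) -> list[Peptide]:
    """Generate the overlapping-peptide tiling of ``seq``.

    Peptide *i* starts at ``step*(i-1)+1``. If the next regular window would
    overrun the C-terminus and ``cfg.anchor_final`` is set, exactly one final
    window ending at the last residue is emitted instead.
    """
    n = len(seq)
    if n < cfg.window_len:
        raise SequenceTooShort(f"sequence length {n} < window {cfg.window_len}")
    peptides: list[Peptide] = []
    index = 1
    start = 1
    while True:
        end = start + cfg.window_len - 1
        if end > n:
            if cfg.anchor_final:
                start, end = n - cfg.window_len + 1, n
                peptides.append(
                    Peptide(index=index, start=start, end=end, sequence=seq.subseq(start, end))
                )
            break
        peptides.append(
            Peptide(index=index, start=start, end=end, sequence=seq.subseq(start, end))
        )
        if end == n:
            break
        index += 1
        start += cfg.step
    return peptides


def _domain_label(start: int, end: int, dmap: DomainMap) -> str:
    hit = [
        k + 1
        for k, (lo, hi) in enumerate(dmap.intervals())
        if start <= hi and end >= lo
    ]
    if len(hit) == 1:
        return str(hit[0])
    return f"{hit[0]}-{hit[-1]}"


def annotate_domains(peptides: Iterable[Peptide], dmap: DomainMap = DomainMap()) -> list[Peptide]:
    """Assign each peptide its domain label from the domain boundary map.

    A peptide lying entirely within one domain interval gets that domain's
    number; a peptide crossing a boundary gets the spanning ``"k-k+1"`` label.
    """
    out: list[Peptide] = []
    last = dmap.domain_ends[-1]
    for p in peptides:
        if p.end > last:
            raise UnmappedSpan(f"peptide {p.index} ends at {p.end}, beyond domain map end {last}")
        out.append(replace(p, domain_label=_domain_label(p.start, p.end, dmap)))
    return out


def find_motif(seq: ProteinSequence, motif: str) -> list[int]:
    """All 1-based start positions of exact (possibly overlapping) matches."""
    if len(motif) == 0:
        raise EmptyMotif("motif must be non-empty")
    return [m.start() + 1 for m in re.finditer(f"(?={re.escape(motif)})", seq.residues)]


def peptide_midpoint(p: Peptide) -> int:
    """Arithmetic midpoint of the inclusive span; even spans round down."""
    return (p.start + p.end) // 2


def infer_domain_boundaries(annotated: Sequence[Peptide]) -> list[set[int]]:
    """Feasible last-residue positions for each adjacent domain boundary.

    For the boundary between domains *k* and *k+1* at residue *b*:
    peptides labelled ``"k"`` require ``end <= b``; peptides labelled
    ``"k+1"`` require ``start > b``; spanning ``"k-k+1"`` peptides require
    ``start <= b < end``. The result intersects all three constraint
    families; an empty intersection means the labels are contradictory.
    """
    labels = {p.domain_label for p in annotated}
    if "" in labels:
        raise InconsistentLabels("peptides must carry domain labels")
    singles = sorted(int(l) for l in labels if "-" not in l)
    if not singles:
        raise InconsistentLabels("no single-domain labels to anchor boundaries")
    n_domains = max(
        max(singles),
        max((int(l.split("-")[1]) for l in labels if "-" in l), default=0),
    )
    out: list[set[int]] = []
    max_end = max(p.end for p in annotated)
    for k in range(1, n_domains):
        lo, hi = 1, max_end
        span_label = f"{k}-{k + 1}"
        for p in annotated:
            if p.domain_label == str(k):
                lo = max(lo, p.end)
            elif p.domain_label == str(k + 1):
                hi = min(hi, p.start - 1)
            elif p.domain_label == span_label:
                lo = max(lo, p.start)
                hi = min(hi, p.end - 1)
        if lo > hi:
            raise InconsistentLabels(f"no feasible boundary between domains {k} and {k + 1}")
        out.append(set(range(lo, hi + 1)))
    return out


# --- I/O --------------------------------------------------------------------

def load_peptide_table(path: str | Path | None = None) -> list[Peptide]:
    """Read a peptide table TSV (columns: peptide_number, sequence, start,
    end, domain). With no path, the packaged 79-peptide β2GP1 table is used."""
    if path is None:
        src = resources.files("pepzone").joinpath("data/peptide_table.tsv")
        with resources.as_file(src) as f:
            df = pd.read_csv(f, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return [
        Peptide(
            index=int(r.peptide_number),
            start=int(r.start),
            end=int(r.end),
            sequence=str(r.sequence),
            domain_label=str(r.domain) if "domain" in df.columns and not pd.isna(r.domain) else "",
        )
        for r in df.itertuples()
    ]


def peptides_to_frame(peptides: Sequence[Peptide]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide_number": [p.index for p in peptides],
            "sequence": [p.sequence for p in peptides],
            "start": [p.start for p in peptides],
            "end": [p.end for p in peptides],
            "domain": [p.domain_label for p in peptides],
        }
    )


def write_peptide_table(peptides: Sequence[Peptide], path: str | Path) -> None:
    peptides_to_frame(peptides).to_csv(path, sep="\t", index=False)


def write_fasta(seq: ProteinSequence, path: str | Path) -> None:
    """Write the protein as single-record FASTA (via Biopython)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(seq.residues), id=seq.id, description="")], str(path), "fasta")


def write_bed(peptides: Sequence[Peptide], path: str | Path, name: str = "antigen") -> None:
    """Export peptide spans as BED-like intervals.

    Coordinates are converted to 0-based half-open only here, at export; the
    header comment flags the convention.
    """
    with open(path, "w") as fh:
        fh.write("# BED-like export: 0-based half-open intervals (converted at export)\n")
        for p in peptides:
            fh.write(f"{name}\t{p.start - 1}\t{p.end}\tP{p.index}\n")
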