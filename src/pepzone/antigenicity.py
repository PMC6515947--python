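"""Antigenicity profiles and high-antigenicity zone detection.

Per-serum binary peptide calls are aggregated into a per-peptide recognition
fraction (the share of sera recognizing each peptide, all sera in the
denominator, including sera that recognize nothing). Peptides recognized by
at least half the sera are *high-antigenicity*; maximal runs of contiguous
high-antigenicity peptides form *zones*, each represented by its
most-recognized member. A near-threshold report lists peptides just below
the cutoff (the "zone 4" pattern: a peptide recognized by 46% of sera).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyMatrix
from .seqcore import Peptide, peptide_midpoint


@dataclass(frozen=True)
class ReactivityMatrix:
    """Sera x peptides binary calls with an optional group label per serum."""

    calls: pd.DataFrame  # index: serum id, columns: peptide index (int), bool
    groups: pd.Series | None = None  # index: serum id

    def __post_init__(self) -> None:
        if self.calls.isna().any().any():
            raise ValueError("reactivity matrix must have no missing cells")
        if self.groups is not None and not self.groups.index.equals(self.calls.index):
            raise ValueError("groups index must match sera index")

    @property
    def n_sera(self) -> int:
        return len(self.calls)

    @property
    def peptide_indices(self) -> list[int]:
        return [int(c) for c in self.calls.columns]


@dataclass(frozen=True)
class AntigenicityProfile:
    """Per-peptide recognition fraction with its constant denominator."""

    fractions: pd.Series  # index: peptide index, values in [0, 1]
    n_sera: int


@dataclass(frozen=True)
class Zone:
    """A maximal run of contiguous high-antigenicity peptides."""

    first_peptide: int
    last_peptide: int
    representative: int
    representative_midpoint: int | None = None
    span_start: int | None = None  # residues, first peptide start
    span_end: int | None = None  # residues, last peptide end
    domains: tuple[str, ...] = ()

    @property
    def peptides(self) -> range:
        return range(self.first_peptide, self.last_peptide + 1)


def recognition_frequency(m: ReactivityMatrix) -> AntigenicityProfile:
    """Fraction of sera recognizing each peptide (all sera in denominator)."""
    if m.n_sera == 0:
        raise EmptyMatrix("reactivity matrix has no sera")
    frac = m.calls.astype(float).mean(axis=0)
    frac.index = pd.Index([int(c) for c in frac.index], name="peptide")
    return AntigenicityProfile(fractions=frac, n_sera=m.n_sera)


def detect_zones(
    profile: AntigenicityProfile,
    threshold: float = 0.5,
    peptides: Sequence[Peptide] | None = None,
) -> list[Zone]:
    """Maximal contiguous runs of peptides with fraction >= threshold.

    Contiguity is in array-index space (peptide i and i+1). Each zone's
    representative is the member with the highest fraction; ties break to
    the lowest peptide index. If ``peptides`` (the tiling) is given, zones
    also carry residue spans, representative midpoints and domain labels.
    """
    frac = profile.fractions.sort_index()
    by_index = {p.index: p for p in peptides} if peptides is not None else {}
    zones: list[Zone] = []
    run: list[int] = []

    def _close(run: list[int]) -> None:
        vals = frac.loc[run]
        rep = int(vals.idxmax())  # idxmax returns the first (lowest) maximizer
        kw: dict = {}
        if by_index:
            kw["representative_midpoint"] = peptide_midpoint(by_index[rep])
            kw["span_start"] = by_index[run[0]].start
            kw["span_end"] = by_index[run[-1]].end
            kw["domains"] = tuple(
                dict.fromkeys(by_index[i].domain_label for i in run if by_index[i].domain_label)
            )
        zones.append(Zone(first_peptide=run[0], last_peptide=run[-1], representative=rep, **kw))

    for idx in frac.index:
        if frac.loc[idx] >= threshold and (not run or idx == run[-1] + 1):
            run.append(int(idx))
        else:
            if run:
                _close(run)
            run = [int(idx)] if frac.loc[idx] >= threshold else []
    if run:
        _close(run)
    return zones


def near_threshold_report(
    profile: AntigenicityProfile, low: float = 0.45, threshold: float = 0.5
) -> list[int]:
    """Peptides with low <= fraction < threshold (just-below-cutoff report)."""
    if not low < threshold:
        raise ValueError("require low < threshold")
    frac = profile.fractions
    return [int(i) for i in frac.index if low <= frac.loc[i] < threshold]


def serum_breadth(m: ReactivityMatrix) -> tuple[pd.Series, pd.Series]:
    """Positive-peptide count per serum, and mean count per group.

    With no group labels the second Series has the single key ``"all"``.
    """
    counts = m.calls.astype(int).sum(axis=1).rename("n_recognized")
    if m.groups is not None:
        means = counts.groupby(m.groups).mean().rename("mean_breadth")
    else:
        means = pd.Series({"all": counts.mean()}, name="mean_breadth")
    return counts, means


# --- I/O --------------------------------------------------------------------

def read_reactivity(path: str | Path) -> ReactivityMatrix:
    """TSV with serum_id, optional group, then one 0/1 column per peptide
    (column names are peptide indices)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index("serum_id")
    groups = None
    if "group" in df.columns:
        groups = df.pop("group").astype(str)
    calls = df.astype(int).astype(bool)
    calls.columns = [int(c) for c in calls.columns]
    return ReactivityMatrix(calls=calls, groups=groups)


def write_reactivity(m: ReactivityMatrix, path: str | Path) -> None:
    out = m.calls.astype(int).copy()
    if m.groups is not None:
        out.insert(0, "group", m.groups)
    out.index.name = "serum_id"
    out.to_csv(path, sep="\t")


def zones_to_frame(zones: Sequence[Zone]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "zone": list(range(1, len(zones) + 1)),
            "first_pep": [z.first_peptide for z in zones],
            "last_pep": [z.last_peptide for z in zones],
            "representative": [z.representative for z in zones],
            "rep_midpoint": [z.representative_midpoint for z in zones],
            "residue_span": [
                f"{z.span_start}-{z.span_end}" if z.span_start is not None else ""
                for z in zones
            ],
            "domains": [",".join(z.domains) for z in zones],
        }
    )


def plot_profile(profile: AntigenicityProfile, path: str | Path, threshold: float = 0.5) -> None:
    """Bar plot of per-peptide recognition percentages (optional, needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(12, 3.5))
    ax.bar(profile.fractions.index, 100 * profile.fractions.values, width=0.8)
    ax.axhline(100 * threshold, color="red", lw=0.8, ls="--")
    ax.set_xlabel("peptide")
    ax.set_ylabel("% sera positive")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
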