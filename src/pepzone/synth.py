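"""Synthetic inputs with the statistical structure the pipeline assumes.

No patient sera or deposited reactivity data exist for this kind of study,
so every stage is exercised on generated data whose ground truth is known:

* ``gen_reactivity`` — a cohort of sera with independent Bernoulli
  peptide calls: three planted high-recognition zones over a polyclonal
  background, an optional near-threshold peptide, and a fraction of sera
  that recognize nothing.
* ``gen_elisa`` — a two-regime serology panel: a majority subgroup whose
  anti-domain-4/5 level follows the whole-molecule anti-β2GP1 level
  linearly (within-group Pearson r ≈ 0.8), and a minority subgroup with
  low, independent anti-domain levels; anti-domain-1 is independent
  throughout.
* ``gen_slide`` — a 16-bit grayscale array image with Gaussian spots on a
  noisy background, plus its layout.
* ``gen_structure`` — alpha-carbon clouds (plane, fish-hook, or coil
  backbones) with planted face-L spans and a mirrored face-J control.

Every generator takes a seed, is fully deterministic given it, and returns
a machine-readable truth record next to the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .antigenicity import ReactivityMatrix
from .array_quant import ArrayLayout, Spot
from .errors import BadSpec, LayoutOverflow
from .structure_map import StructureModel

#: Planted zones of the default cohort: peptide spans with elevated
#: recognition probability (the three immunodominant zones).
DEFAULT_ZONES: tuple[tuple[int, int, float], ...] = (
    (33, 35, 0.7),
    (46, 52, 0.7),
    (62, 67, 0.7),
)


@dataclass(frozen=True)
class CohortSpec:
    """Generative model of per-serum binary peptide reactivity.

    Probabilities are cohort marginals: the expected recognition fraction
    over *all* sera (including forced all-zero sera) equals the planted
    probability, so reactive sera use ``p / (1 - zero_fraction)``.
    """

    n_sera: int = 93
    n_peptides: int = 79
    zones: tuple[tuple[int, int, float], ...] = DEFAULT_ZONES  # (first, last, p)
    background_p: float = 0.2
    near_threshold: tuple[int, float] | None = (14, 0.46)  # (peptide, p)
    zero_fraction: float = 5 / 93
    groups: tuple[tuple[str, int], ...] = (("CKD", 50), ("NKF", 43))
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.background_p, self.zero_fraction] + [p for _, _, p in self.zones]
        if self.near_threshold:
            probs.append(self.near_threshold[1])
        if any(not 0 <= p <= 1 for p in probs):
            raise BadSpec("probabilities must lie in [0, 1]")
        for first, last, _ in self.zones:
            if not 1 <= first <= last <= self.n_peptides:
                raise BadSpec(f"zone span {first}-{last} outside 1..{self.n_peptides}")
        if self.groups and sum(n for _, n in self.groups) != self.n_sera:
            raise BadSpec("group sizes must sum to n_sera")


@dataclass(frozen=True)
class ElisaMixtureSpec:
    """Two-regime anti-β2GP1 / anti-domain panel generator.

    Whole-molecule IgA anti-β2GP1 levels are log-normal, matched to a
    median of 60.8 U and an interquartile range of 40.1–121 U. In the
    correlated subgroup anti-D4/5 = intercept + slope·anti-β2GP1 + noise,
    with heteroscedastic Gaussian noise proportional to the expected level
    (immunoassay error is approximately constant-CV, not constant-SD) and
    an overall magnitude scaled to hit ``target_r`` within the subgroup.
    In the uncorrelated subgroup anti-D4/5 is an independent low-level
    log-normal (the anti-D4/5-nonreactive band). Anti-D1 is independent of
    everything.
    """

    n: int = 93
    correlated_frac: float = 66 / 93
    target_r: float = 0.8
    b2gp1_median: float = 60.8
    b2gp1_iqr: tuple[float, float] = (40.1, 121.0)
    link_intercept: float = 15.0
    link_slope: float = 0.6
    uncorr_median: float = 8.0
    uncorr_sigma: float = 0.6
    d1_median: float = 10.0
    d1_sigma: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.correlated_frac <= 1:
            raise BadSpec("correlated_frac must lie in [0, 1]")
        if not -1 < self.target_r <= 1:
            raise BadSpec("target_r must lie in (-1, 1]")
        if self.b2gp1_iqr[0] >= self.b2gp1_iqr[1]:
            raise BadSpec("IQR bounds must increase")


@dataclass(frozen=True)
class SlideSpec:
    """Geometry and noise model of a synthetic array slide."""

    n_rows: int = 7
    n_cols: int = 12
    pitch: int = 24  # px between spot centers
    radius: float = 6.0
    margin: int = 16
    background_mean: float = 500.0
    background_sd: float = 50.0
    amplitude: float = 3000.0  # peak height of a bound spot
    psf_sigma: float = 3.0
    n_peptides: int = 79
    n_negatives: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols < self.n_peptides + self.n_negatives:
            raise LayoutOverflow("grid too small for peptide + negative spots")
        if self.background_mean + self.amplitude > 65535:
            raise BadSpec("expected intensities exceed 16-bit range")

    @property
    def image_shape(self) -> tuple[int, int]:
        return (
            2 * self.margin + (self.n_rows - 1) * self.pitch + 1,
            2 * self.margin + (self.n_cols - 1) * self.pitch + 1,
        )


def gen_reactivity(spec: CohortSpec = CohortSpec()) -> tuple[ReactivityMatrix, dict]:
    """Draw a sera x peptides binary reactivity matrix with planted zones."""
    rng = np.random.default_rng(spec.seed)
    p = np.full(spec.n_peptides, spec.background_p)
    for first, last, pz in spec.zones:
        p[first - 1 : last] = pz
    if spec.near_threshold:
        pep, pv = spec.near_threshold
        p[pep - 1] = pv
    n_zero = int(round(spec.zero_fraction * spec.n_sera))
    # reactive sera compensate so the all-sera marginal equals the planted p
    scale = 1.0 if spec.n_sera == n_zero else spec.n_sera / (spec.n_sera - n_zero)
    p_reactive = np.clip(p * scale, 0.0, 1.0)
    calls = rng.random((spec.n_sera, spec.n_peptides)) < p_reactive
    zero_rows = rng.choice(spec.n_sera, size=n_zero, replace=False)
    calls[zero_rows] = False
    sera = [f"S{i + 1:03d}" for i in range(spec.n_sera)]
    groups = None
    if spec.groups:
        labels = [g for g, n in spec.groups for _ in range(n)]
        groups = pd.Series(labels, index=sera, name="group")
    df = pd.DataFrame(calls, index=pd.Index(sera, name="serum_id"),
                      columns=range(1, spec.n_peptides + 1))
    truth = {
        "zones": [(f, l) for f, l, _ in spec.zones],
        "zone_p": [pz for _, _, pz in spec.zones],
        "background_p": spec.background_p,
        "near_threshold": spec.near_threshold,
        "zero_sera": sorted(sera[i] for i in zero_rows),
        "seed": spec.seed,
    }
    return ReactivityMatrix(calls=df, groups=groups), truth


def gen_elisa(spec: ElisaMixtureSpec = ElisaMixtureSpec()) -> tuple[pd.DataFrame, dict]:
    """Draw a serology panel with a correlated and an uncorrelated regime.

    Returns a DataFrame (index serum id; columns anti_b2gp1_iga,
    anti_d45_iga, anti_d1_iga) and a truth record with the subgroup
    membership mask.
    """
    rng = np.random.default_rng(spec.seed)
    mu = float(np.log(spec.b2gp1_median))
    sigma = float(np.log(spec.b2gp1_iqr[1] / spec.b2gp1_iqr[0]) / (2 * 0.6744898))
    x = rng.lognormal(mean=mu, sigma=sigma, size=spec.n)
    n_corr = int(round(spec.correlated_frac * spec.n))
    correlated = np.zeros(spec.n, dtype=bool)
    correlated[rng.choice(spec.n, size=n_corr, replace=False)] = True

    y = np.empty(spec.n)
    if n_corr:
        xs = x[correlated]
        mean_y = spec.link_intercept + spec.link_slope * xs
        signal_var = (spec.link_slope**2) * float(np.var(xs, ddof=1)) if n_corr > 1 else 0.0
        if spec.target_r >= 1.0 or signal_var == 0.0:
            cv = 0.0
        else:
            # total noise variance chosen so the within-group r hits target_r;
            # spread across sera proportionally to the expected level
            noise_var = signal_var * (1 / spec.target_r**2 - 1)
            cv = float(np.sqrt(noise_var / np.mean(mean_y**2)))
        y[correlated] = mean_y + rng.normal(0.0, cv * mean_y)
    n_unc = spec.n - n_corr
    if n_unc:
        y[~correlated] = rng.lognormal(
            mean=float(np.log(spec.uncorr_median)), sigma=spec.uncorr_sigma, size=n_unc
        )
    y = np.maximum(y, 0.0)
    d1 = rng.lognormal(mean=float(np.log(spec.d1_median)), sigma=spec.d1_sigma, size=spec.n)
    sera = [f"S{i + 1:03d}" for i in range(spec.n)]
    panel = pd.DataFrame(
        {"anti_b2gp1_iga": x, "anti_d45_iga": y, "anti_d1_iga": d1},
        index=pd.Index(sera, name="serum_id"),
    )
    truth = {
        "correlated": correlated,
        "n_correlated": int(n_corr),
        "target_r": spec.target_r,
        "seed": spec.seed,
    }
    return panel, truth


def gen_layout(spec: SlideSpec = SlideSpec()) -> ArrayLayout:
    """Row-major grid layout: peptide spots first, then negatives."""
    spots = []
    k = 0
    for i in range(spec.n_rows):
        for j in range(spec.n_cols):
            if k >= spec.n_peptides + spec.n_negatives:
                break
            row = spec.margin + i * spec.pitch
            col = spec.margin + j * spec.pitch
            if k < spec.n_peptides:
                spots.append(
                    Spot(f"P{k + 1}", "peptide", row, col, spec.radius, peptide_index=k + 1)
                )
            else:
                spots.append(Spot(f"N{k - spec.n_peptides + 1}", "negative", row, col, spec.radius))
            k += 1
    return ArrayLayout(spots=tuple(spots))


def gen_slide(
    spec: SlideSpec = SlideSpec(), bound_peptides: Sequence[int] = ()
) -> tuple[np.ndarray, ArrayLayout, dict]:
    """Render a synthetic 16-bit slide: Gaussian spots plus background noise.

    ``bound_peptides`` get the full spot amplitude; unbound peptide spots
    and negative spots get none (background only).
    """
    layout = gen_layout(spec)
    h, w = spec.image_shape
    rng = np.random.default_rng(spec.seed)
    img = rng.normal(spec.background_mean, spec.background_sd, size=(h, w))
    bound = set(bound_peptides)
    if not bound.issubset(range(1, spec.n_peptides + 1)):
        raise BadSpec("bound_peptides outside 1..n_peptides")
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    for s in layout.spots:
        if s.role == "peptide" and s.peptide_index in bound:
            d2 = (rr - s.row) ** 2 + (cc - s.col) ** 2
            img += spec.amplitude * np.exp(-d2 / (2 * spec.psf_sigma**2))
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    truth = {"bound_peptides": sorted(bound), "seed": spec.seed}
    return img, layout, truth


def gen_structure(
    n_res: int = 100,
    shape: str = "fishhook",
    l_side_spans: Sequence[tuple[int, int]] = ((30, 40),),
    j_side_spans: Sequence[tuple[int, int]] = (),
    displacement: float = 5.0,
    noise: float = 0.3,
    edge_delta: float = 1.5,
    seed: int = 0,
) -> tuple[StructureModel, pd.Series]:
    """Alpha-carbon cloud with known face sidedness per residue.

    The backbone traces a curve in the x-y plane — a straight line
    (``plane``), an L-shaped fish-hook (``fishhook``), or a flat coil
    (``helix``) — with small Gaussian z-jitter, so the least-variance
    direction of the cloud is z. Residues in ``l_side_spans`` are displaced
    to z = +``displacement`` and ``j_side_spans`` to -``displacement``.
    Truth labels derive from each residue's final z: L above ``edge_delta``,
    J below -``edge_delta``, edge within the band.
    """
    for first, last in list(l_side_spans) + list(j_side_spans):
        if not 1 <= first <= last <= n_res:
            raise BadSpec(f"span {first}-{last} outside 1..{n_res}")
    rng = np.random.default_rng(seed)
    t = np.arange(n_res, dtype=float)
    if shape == "plane":
        # serpentine sheet: rows of 10 residues filling the x-y plane
        x, y = 3.8 * (t % 10), 3.8 * (t // 10)
    elif shape == "fishhook":
        # vertical arm then horizontal foot, like an open fish-hook seen flat
        elbow = int(0.7 * n_res)
        x = np.where(t < elbow, 0.0, 3.8 * (t - elbow))
        y = np.where(t < elbow, 3.8 * (elbow - t), 0.0)
    elif shape == "helix":
        x, y = 12.0 * np.cos(t / 3), 40.0 + 8.0 * np.sin(t / 3) + 1.2 * t
    else:
        raise BadSpec(f"unknown shape '{shape}'")
    z = rng.normal(0.0, noise, size=n_res)
    for first, last in l_side_spans:
        z[first - 1 : last] = displacement + rng.normal(0.0, noise, size=last - first + 1)
    for first, last in j_side_spans:
        z[first - 1 : last] = -displacement + rng.normal(0.0, noise, size=last - first + 1)
    coords = {i + 1: np.array([x[i], y[i], z[i]]) for i in range(n_res)}
    truth_labels = np.where(z > edge_delta, "L", np.where(z < -edge_delta, "J", "edge"))
    truth = pd.Series(
        truth_labels, index=pd.Index(range(1, n_res + 1), name="residue"), name="face"
    )
    return StructureModel(chain_id="A", coords=coords), truth


def structure_to_pdb(model: StructureModel) -> str:
    """Serialize a CA-only model as PDB text (synthetic fixtures, round-trips
    through :func:`pepzone.structure_map.read_structure`)."""
    lines = []
    for serial, res in enumerate(sorted(model.coords), start=1):
        x, y, z = model.coords[res]
        lines.append(
            f"ATOM  {serial:5d}  CA  GLY {model.chain_id}{res:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
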