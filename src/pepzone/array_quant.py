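"""Fixed-circle spot quantification and positivity calling for peptide arrays.

Slides carry one spot per tiled peptide plus at least five negative spots
(no peptide). Scanned images are 16-bit grayscale; each spot's signal is the
integrated optical density (IOD): the sum of pixel intensities whose centers
fall inside a fixed circle at the expected spot position. No adaptive
segmentation or morphology QC is performed — the fixed circle is the method.

A peptide is called positive when its IOD exceeds a per-slide threshold:
the mean IOD of the negative spots plus ``k`` (default 2) times the sample
standard deviation of the IODs of ``n_random`` (default 15) randomly sampled
peptide spots. Under a Gaussian null this leaves >95% of null spots uncalled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CircleOutOfBounds,
    EmptyCircle,
    InsufficientNegatives,
    InsufficientPeptides,
)

Role = Literal["peptide", "negative", "control"]


@dataclass(frozen=True)
class Spot:
    spot_id: str
    role: Role
    row: float  # center, pixels
    col: float
    radius: float
    peptide_index: int | None = None  # set for role == "peptide"


@dataclass(frozen=True)
class ArrayLayout:
    spots: tuple[Spot, ...]

    def __post_init__(self) -> None:
        ids = [s.spot_id for s in self.spots]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate spot ids")

    def by_role(self, role: Role) -> list[Spot]:
        return [s for s in self.spots if s.role == role]


@dataclass(frozen=True)
class SpotQuant:
    spot_id: str
    role: Role
    iod: float
    peptide_index: int | None = None


@dataclass(frozen=True)
class ThresholdModel:
    """Background-plus-k·SD positivity threshold for one slide."""

    neg_mean: float
    rand_sd: float
    k: float
    sampled_ids: tuple[str, ...]
    seed: int

    @property
    def threshold(self) -> float:
        return self.neg_mean + self.k * self.rand_sd


def _circle_mask(shape: tuple[int, int], row: float, col: float, radius: float) -> np.ndarray:
    rr = np.arange(shape[0])[:, None] - row
    cc = np.arange(shape[1])[None, :] - col
    return rr * rr + cc * cc <= radius * radius


def measure_iod(
    image: np.ndarray,
    layout: ArrayLayout,
    invert: bool = False,
) -> list[SpotQuant]:
    """Integrated optical density of every layout spot.

    A pixel belongs to a spot when its center lies within the circle
    (``(r-row)^2 + (c-col)^2 <= radius^2``). ``invert`` flips a 16-bit image
    (``65535 - value``) for optical-density-style scans where darker means
    more binding.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if invert:
        img = 65535 - img.astype(np.int64)
    quants: list[SpotQuant] = []
    h, w = img.shape
    for s in layout.spots:
        if s.row - s.radius < -0.5 or s.row + s.radius > h - 0.5 or \
           s.col - s.radius < -0.5 or s.col + s.radius > w - 0.5:
            raise CircleOutOfBounds(f"spot {s.spot_id} circle outside {h}x{w} image")
        mask = _circle_mask(img.shape, s.row, s.col, s.radius)
        if not mask.any():
            raise EmptyCircle(f"spot {s.spot_id}: no pixel center within radius {s.radius}")
        quants.append(
            SpotQuant(
                spot_id=s.spot_id,
                role=s.role,
                iod=float(img[mask].sum(dtype=np.float64)),
                peptide_index=s.peptide_index,
            )
        )
    return quants


def compute_threshold(
    quants: Sequence[SpotQuant],
    n_random: int = 15,
    k: float = 2.0,
    seed: int = 0,
    use_all_peptides: bool = False,
) -> ThresholdModel:
    """Per-slide positivity threshold: mean(negatives) + k * SD(sampled peptides).

    ``n_random`` peptide spots are sampled without replacement with a seeded
    generator and recorded in ``sampled_ids``; ``use_all_peptides`` replaces
    the sample by every peptide spot. SD uses the n-1 denominator.
    """
    negatives = [q.iod for q in quants if q.role == "negative"]
    peptides = [q for q in quants if q.role == "peptide"]
    if len(negatives) < 5:
        raise InsufficientNegatives(f"need >=5 negative spots, got {len(negatives)}")
    if use_all_peptides:
        sampled = list(peptides)
    else:
        if len(peptides) < n_random:
            raise InsufficientPeptides(f"need >={n_random} peptide spots, got {len(peptides)}")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(peptides), size=n_random, replace=False)
        sampled = [peptides[i] for i in sorted(idx)]
    sd = float(np.std([q.iod for q in sampled], ddof=1)) if len(sampled) > 1 else 0.0
    return ThresholdModel(
        neg_mean=float(np.mean(negatives)),
        rand_sd=sd,
        k=k,
        sampled_ids=tuple(q.spot_id for q in sampled),
        seed=seed,
    )


def call_positive(quants: Sequence[SpotQuant], model: ThresholdModel) -> pd.Series:
    """Binary positivity per peptide: IOD strictly above the threshold.

    Returns a Series indexed by peptide index (equal IOD and threshold is
    negative — the comparison is strict).
    """
    peptides = [q for q in quants if q.role == "peptide"]
    idx = [q.peptide_index if q.peptide_index is not None else i + 1 for i, q in enumerate(peptides)]
    calls = [q.iod > model.threshold for q in peptides]
    return pd.Series(calls, index=pd.Index(idx, name="peptide"), name="positive", dtype=bool)


# --- I/O --------------------------------------------------------------------

def read_image(path: str | Path, invert: bool = False) -> np.ndarray:
    """Read a 16-bit grayscale PNG or TIFF as a 2-D integer array."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        img = tifffile.imread(path)
    else:
        from PIL import Image

        img = np.asarray(Image.open(path))
    img = np.asarray(img)
    if invert:
        img = 65535 - img.astype(np.int64)
    return img


def write_image(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    arr = np.asarray(image, dtype=np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr.astype(np.uint32), mode="I").convert("I;16").save(path)


def read_layout(path: str | Path) -> ArrayLayout:
    """Layout TSV with columns spot_id, role, row, col, radius
    (and optional peptide_index)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    spots = []
    for r in df.itertuples():
        pidx = getattr(r, "peptide_index", None)
        spots.append(
            Spot(
                spot_id=str(r.spot_id),
                role=str(r.role),  # type: ignore[arg-type]
                row=float(r.row),
                col=float(r.col),
                radius=float(r.radius),
                peptide_index=None if pidx is None or pd.isna(pidx) else int(pidx),
            )
        )
    return ArrayLayout(spots=tuple(spots))


def write_layout(layout: ArrayLayout, path: str | Path) -> None:
    pd.DataFrame(
        {
            "spot_id": [s.spot_id for s in layout.spots],
            "role": [s.role for s in layout.spots],
            "row": [s.row for s in layout.spots],
            "col": [s.col for s in layout.spots],
            "radius": [s.radius for s in layout.spots],
            "peptide_index": [s.peptide_index for s in layout.spots],
        }
    ).to_csv(path, sep="\t", index=False)


def quants_to_frame(quants: Sequence[SpotQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spot_id": [q.spot_id for q in quants],
            "role": [q.role for q in quants],
            "peptide_index": [q.peptide_index for q in quants],
            "iod": [q.iod for q in quants],
        }
    )
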