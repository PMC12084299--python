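"""Image preprocessing and per-cell quantification.

The preprocessing chain mirrors standard IMC practice and is applied in a
fixed, logged order: spillover compensation -> median denoising -> linear
intensity adjustment -> per-cell quantification against a segmentation
label mask. Segmentation itself (e.g. a pretrained TissueNet model) is out
of scope; this module consumes integer label masks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

#: fixed stage order of the preprocessing chain
PIPELINE_ORDER = ("compensate_spillover", "denoise_median", "adjust_intensity_linear", "quantify_cells")

# condition number above which the direct linear solve is abandoned and
# every pixel goes through explicit non-negative least squares
_COND_THRESHOLD = 1e8


@dataclass
class SegmentedROI:
    """One acquisition window: a multichannel stack plus its label mask.

    ``intensities`` is channels x H x W (non-negative, finite);
    ``mask`` is H x W with 0 = background and positive integers = cells.
    """

    intensities: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    channel_names: list[str]
    roi_id: str
    sample_id: str = ""
    group: str = ""
    pixel_size: float = 1.0  # um per pixel

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.mask = np.asarray(self.mask)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be channels x H x W")
        if self.intensities.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.intensities.shape[0]} channels but "
                f"{len(self.channel_names)} channel names"
            )
        if self.mask.shape != self.intensities.shape[1:]:
            raise ValueError("mask shape does not match image planes")
        if self.mask.min(initial=0) < 0:
            raise ValueError("mask labels must be non-negative")
        if not np.all(np.isfinite(self.intensities)) or self.intensities.min(initial=0) < 0:
            raise ValueError("intensities must be finite and non-negative")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def labels(self) -> np.ndarray:
        lab = np.unique(self.mask)
        return lab[lab > 0]


@dataclass
class SpilloverMatrix:
    """Square channel-crosstalk matrix.

    ``matrix[i, j]`` is the fraction of channel *i* signal observed in
    channel *j*; the diagonal is exactly 1 (rows indexed by source channel).
    """

    matrix: np.ndarray
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("spillover matrix must be square")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("spillover diagonal must be exactly 1")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("spillover entries must lie in [0, 1]")
        self.matrix = m

    @classmethod
    def identity(cls, n: int, channel_names: list[str] | None = None) -> "SpilloverMatrix":
        return cls(np.eye(n), channel_names)

    @classmethod
    def from_csv(cls, path) -> "SpilloverMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(dtype=float), list(frame.columns))

    def to_csv(self, path) -> None:
        names = self.channel_names or [f"ch{i}" for i in range(len(self.matrix))]
        pd.DataFrame(self.matrix, index=names, columns=names).to_csv(path)

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.matrix, np.eye(len(self.matrix)))


def forward_spillover(roi: SegmentedROI, spillover: SpilloverMatrix) -> SegmentedROI:
    """Apply the spillover forward model (observed = S^T true). Test utility."""
    s = spillover.matrix
    if s.shape[0] != roi.n_channels:
        raise ValueError("spillover dimension does not match channel count")
    mixed = np.einsum("ij,ihw->jhw", s, roi.intensities.astype(float))
    return replace(roi, intensities=mixed)


def compensate_spillover(roi: SegmentedROI, spillover: SpilloverMatrix) -> SegmentedROI:
    """Unmix channel crosstalk by per-pixel non-negative least squares.

    Each observed pixel vector ``o`` is replaced by
    ``argmin_{x >= 0} || S^T x - o ||^2``. For a well-conditioned square S
    the exact linear solution has zero residual, so whenever it is already
    non-negative it *is* the NNLS optimum and is used directly; only pixels
    with negative components (or every pixel, for ill-conditioned S) go
    through the iterative NNLS solver.
    """
    s = spillover.matrix
    c = roi.n_channels
    if s.shape[0] != c:
        raise ValueError(
            f"spillover matrix is {s.shape[0]}x{s.shape[1]} but ROI has {c} channels"
        )
    if spillover.is_identity:
        return replace(roi, intensities=roi.intensities.copy())

    obs = roi.intensities.reshape(c, -1).astype(float)  # c x npix
    st = s.T
    cond = np.linalg.cond(st)
    if cond > _COND_THRESHOLD:
        warnings.warn(
            f"spillover matrix is ill-conditioned (cond={cond:.3g}); "
            "falling back to per-pixel NNLS for every pixel",
            RuntimeWarning,
            stacklevel=2,
        )
        unmixed = np.empty_like(obs)
        for p in range(obs.shape[1]):
            unmixed[:, p] = nnls(st, obs[:, p])[0]
    else:
        unmixed = np.linalg.solve(st, obs)
        bad = np.flatnonzero((unmixed < 0).any(axis=0))
        for p in bad:
            unmixed[:, p] = nnls(st, obs[:, p])[0]
    unmixed = np.maximum(unmixed, 0.0)
    logger.info("compensate_spillover: refined %d pixels via NNLS", 0 if cond > _COND_THRESHOLD else len(bad))
    return replace(roi, intensities=unmixed.reshape(roi.intensities.shape))


def denoise_median(roi: SegmentedROI, window: int = 3) -> SegmentedROI:
    """Per-channel 2-D median filter with reflecting edge handling."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"median window must be odd and >= 1, got {window}")
    if window == 1:
        return replace(roi, intensities=roi.intensities.copy())
    out = np.stack(
        [ndimage.median_filter(ch, size=window, mode="reflect") for ch in roi.intensities]
    )
    return replace(roi, intensities=out)


def adjust_intensity_linear(
    roi: SegmentedROI, low_pct: float = 1.0, high_pct: float = 99.0
) -> SegmentedROI:
    """Linear contrast adjustment per channel.

    The ``low_pct`` percentile maps to 0 and the ``high_pct`` percentile to
    its own (pre-adjustment) value; output is clipped to that range, so the
    rank order of pixels within a channel is preserved. Percentiles are
    computed over the whole channel, background included. A degenerate
    channel (all values equal) is returned unchanged with a warning.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    out = roi.intensities.astype(float).copy()
    for ci in range(roi.n_channels):
        ch = out[ci]
        lo, hi = np.percentile(ch, [low_pct, high_pct])
        if hi == lo:
            warnings.warn(
                f"channel {roi.channel_names[ci]!r} is degenerate under "
                f"({low_pct}, {high_pct}) percentiles; left unchanged",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        out[ci] = np.clip((ch - lo) / (hi - lo), 0.0, 1.0) * hi
    return replace(roi, intensities=out)


def quantify_cells(roi: SegmentedROI, statistic: str = "mean") -> pd.DataFrame:
    """Aggregate pixel intensities per mask label into a raw cell table.

    Returns one row per label (ordered by label) with the per-channel
    ``statistic`` over the label's pixels, the intensity-unweighted centroid
    (x = column, y = row, 0-based) and the pixel area. An empty mask yields
    an empty table.
    """
    if statistic not in ("mean", "median", "sum"):
        raise ValueError(f"unknown statistic {statistic!r}")
    labels = roi.labels()
    cols = ["cell_id", "roi_id", "sample_id", "group", "x", "y", "area"] + list(roi.channel_names)
    if labels.size == 0:
        return pd.DataFrame(columns=cols)

    mask = roi.mask
    flat = mask.ravel()
    nmax = int(labels.max()) + 1
    counts = np.bincount(flat, minlength=nmax)
    yy, xx = np.indices(mask.shape)
    cx = np.bincount(flat, weights=xx.ravel(), minlength=nmax)[labels] / counts[labels]
    cy = np.bincount(flat, weights=yy.ravel(), minlength=nmax)[labels] / counts[labels]

    values = np.empty((labels.size, roi.n_channels))
    if statistic == "median":
        for ci, ch in enumerate(roi.intensities):
            values[:, ci] = ndimage.labeled_comprehension(
                ch, mask, labels, np.median, float, np.nan
            )
    else:
        for ci, ch in enumerate(roi.intensities):
            sums = np.bincount(flat, weights=ch.ravel().astype(float), minlength=nmax)[labels]
            values[:, ci] = sums if statistic == "sum" else sums / counts[labels]

    table = pd.DataFrame(
        {
            "cell_id": labels.astype(int),
            "roi_id": roi.roi_id,
            "sample_id": roi.sample_id,
            "group": roi.group,
            "x": cx,
            "y": cy,
            "area": counts[labels].astype(int),
        }
    )
    table[roi.channel_names] = values
    return table


def preprocess_and_quantify(
    roi: SegmentedROI,
    spillover: SpilloverMatrix | None = None,
    median_window: int = 3,
    adjust: tuple[float, float] | None = (1.0, 99.0),
    statistic: str = "mean",
) -> pd.DataFrame:
    """Run the full fixed-order chain on one ROI and return its cell table.

    ``spillover=None`` means no compensation (identity matrix) — compensation
    is never invented when no matrix is supplied.
    """
    logger.info("preprocess %s: order %s", roi.roi_id, " -> ".join(PIPELINE_ORDER))
    if spillover is not None:
        roi = compensate_spillover(roi, spillover)
    roi = denoise_median(roi, median_window)
    if adjust is not None:
        roi = adjust_intensity_linear(roi, *adjust)
    return quantify_cells(roi, statistic=statistic)


def read_roi(image_path, mask_path, channel_names, **meta) -> SegmentedROI:
    """Load an OME-TIFF stack and a label-mask TIFF into a SegmentedROI."""
    stack = tifffile.imread(image_path)
    mask = tifffile.imread(mask_path)
    if stack.ndim == 2:
        stack = stack[None]
    return SegmentedROI(stack.astype(np.float32), mask.astype(np.int32), list(channel_names), **meta)


def write_roi(roi: SegmentedROI, image_path, mask_path) -> None:
    """Write the intensity stack as OME-TIFF and the mask as uint16 TIFF."""
    tifffile.imwrite(
        image_path,
        roi.intensities.astype(np.float32),
        ome=True,
        metadata={"axes": "CYX", "Channel": {"Name": list(roi.channel_names)}},
    )
    tifffile.imwrite(mask_path, roi.mask.astype(np.uint16))
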