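"""Per-voxel missingness patterns and voxel-specific zero-ed designs.

Near cortical boundaries different subjects contribute data at different
voxels, so each voxel v has its own diagonal 0/1 "missingness matrix" M_v.
Zero-ing out the design rows where a voxel lacks data (with the missing
response entries encoded as 0) makes the analysis proceed exactly as if
those rows had been deleted, while keeping a common row frame across voxels.
Voxels sharing an identical pattern can share every design-dependent
quantity, so patterns are grouped.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

__all__ = [
    "MissingnessPattern",
    "PatternGroup",
    "compute_missingness",
    "apply_missingness_threshold",
    "zero_out_rows",
    "group_by_pattern",
]


class MaskError(ValueError):
    """Raised for inconsistent image/mask geometry or thresholds."""


@dataclass(frozen=True)
class MissingnessPattern:
    """Indicator vector m_v (diagonal of M_v) and observation count n_v."""

    indicator: np.ndarray  # (n,) uint8, 1 = observed

    @property
    def n_obs(self) -> int:
        return int(self.indicator.sum())


@dataclass
class PatternGroup:
    """A missingness pattern plus the voxel indices sharing it."""

    pattern: MissingnessPattern
    voxels: np.ndarray  # indices into the voxel axis


def compute_missingness(
    data: np.ndarray,
    analysis_mask: np.ndarray,
    per_image_masks: np.ndarray | None = None,
) -> np.ndarray:
    """Per-voxel observation indicators for a stack of response images.

    Parameters
    ----------
    data:
        (n, n_voxels) response values, one row per image, restricted to the
        analysis-mask voxels (see :mod:`voxlmm.pipeline` for NIfTI handling).
    analysis_mask:
        (n_voxels,) boolean; voxels outside are excluded entirely.
    per_image_masks:
        Optional (n, n_voxels) boolean array of user-supplied per-image masks.

    Returns
    -------
    (n, n_voxels) uint8 indicator array: entry [i, v] is 0 iff voxel v is
    treated as missing in image i — outside the image's mask, or exactly 0 or
    NaN in the data (implicit masking).
    """
    data = np.asarray(data)
    if data.ndim != 2:
        raise MaskError("data must be (n_images, n_voxels)")
    obs = np.isfinite(data) & (data != 0.0)
    if per_image_masks is not None:
        per_image_masks = np.asarray(per_image_masks, dtype=bool)
        if per_image_masks.shape != data.shape:
            raise MaskError(
                f"per-image masks shape {per_image_masks.shape} does not "
                f"match data shape {data.shape}"
            )
        obs &= per_image_masks
    obs &= np.asarray(analysis_mask, dtype=bool)[None, :]
    return obs.astype(np.uint8)


def apply_missingness_threshold(
    indicators: np.ndarray, threshold, n_images: int | None = None
) -> np.ndarray:
    """Boolean mask of voxels retained under the missingness threshold.

    ``threshold`` is either a percentage string/float in (0, 100] (e.g.
    ``"50%"`` or ``50.0`` with ``percent=True`` semantics — any float <= 100
    given as a string ending in '%') or an integer count in 1..n.  A voxel is
    retained iff n_v >= ceil(threshold% * n / 100) (percentage form, boundary
    inclusive) or n_v >= threshold (count form).
    """
    indicators = np.asarray(indicators)
    n = n_images if n_images is not None else indicators.shape[0]
    n_v = indicators.sum(axis=0)

    if isinstance(threshold, str):
        if not threshold.endswith("%"):
            raise MaskError(f"string threshold must end in '%': {threshold!r}")
        pct = float(threshold[:-1])
        if not 0.0 < pct <= 100.0:
            raise MaskError(f"percentage threshold outside (0, 100]: {pct}")
        count = math.ceil(pct * n / 100.0)
    elif isinstance(threshold, (int, np.integer)):
        count = int(threshold)
        if not 1 <= count <= n:
            raise MaskError(f"integer threshold outside 1..{n}: {count}")
    elif isinstance(threshold, float):
        if not 0.0 < threshold <= 100.0:
            raise MaskError(f"percentage threshold outside (0, 100]: {threshold}")
        count = math.ceil(threshold * n / 100.0)
    else:
        raise MaskError(f"unsupported threshold type: {type(threshold)}")
    return n_v >= count


def zero_out_rows(
    X: np.ndarray, Z: np.ndarray | None, m_v: np.ndarray
) -> tuple[np.ndarray, np.ndarray | None]:
    """Voxel-specific designs X_v = M_v X, Z_v = M_v Z (rows zero-ed)."""
    m = np.asarray(m_v, dtype=np.float64).ravel()
    if m.shape[0] != X.shape[0]:
        raise MaskError("indicator length does not match design rows")
    X_v = X * m[:, None]
    Z_v = None if Z is None else Z * m[:, None]
    return X_v, Z_v


def group_by_pattern(indicators: np.ndarray) -> list[PatternGroup]:
    """Partition voxels into groups sharing an identical missingness pattern.

    Exactness is guaranteed by keying on the raw pattern bytes; cost is
    O(n_voxels * n / 8).  Group order follows first appearance so results
    are deterministic.
    """
    indicators = np.asarray(indicators, dtype=np.uint8)
    n, n_vox = indicators.shape
    packed = np.packbits(indicators, axis=0)
    groups: dict[bytes, list[int]] = {}
    for v in range(n_vox):
        groups.setdefault(packed[:, v].tobytes(), []).append(v)
    out = []
    for key, voxels in groups.items():
        first = voxels[0]
        out.append(
            PatternGroup(
                pattern=MissingnessPattern(indicators[:, first].copy()),
                voxels=np.asarray(voxels, dtype=np.int64),
            )
        )
    return out
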