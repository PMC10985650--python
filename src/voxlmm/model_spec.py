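"""Design specification for the mass-univariate linear mixed model.

The model fitted at every voxel is

    Y = X beta + Z b + eps,   eps ~ N(0, sigma^2 I),   b ~ N(0, sigma^2 D),

where ``X`` (n x p) holds the fixed-effects regressors and ``Z`` (n x q) the
random-effects regressors.  Random effects are organised by *factors*
(grouping categorical variables) and *levels* (their categories): factor k
groups q_k random-effect regressors into l_k levels, contributing a block of
l_k * q_k columns to ``Z`` and a block-diagonal contribution
``I_{l_k} (x) D_k`` to the (sigma^2-relative) covariance ``D``.

Columns are ordered level-major within each factor (all q_k effects of level
1, then level 2, ...), factors in user-given order; every downstream module
(covariance assembly, Fisher-scoring score vectors) relies on this single
convention, which matches the vec(D_k) parameter ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "ModelSpec",
    "CovarianceBlocks",
    "build_indicator_matrix",
    "build_random_design",
    "assemble_full_D",
    "load_design_matrix",
    "load_factor_vector",
]


class DesignError(ValueError):
    """Raised for invalid design specifications."""


def _normalise_labels(raw) -> tuple[np.ndarray, list]:
    """Map arbitrary labels to dense integers 1..l in first-appearance order.

    Returns the normalised vector and the ordered list of original labels
    (position j holds the label mapped to level j+1).
    """
    raw = np.asarray(raw).ravel()
    mapping: dict = {}
    out = np.empty(raw.shape[0], dtype=np.int64)
    for i, lab in enumerate(raw):
        key = lab.item() if isinstance(lab, np.generic) else lab
        if key not in mapping:
            mapping[key] = len(mapping) + 1
        out[i] = mapping[key]
    return out, list(mapping)


@dataclass
class FactorSpec:
    """One random-effects factor: grouping vector plus raw regressors.

    Parameters
    ----------
    factor_vector:
        Length-n vector of level labels.  Arbitrary hashable labels are
        accepted and normalised to dense integers 1..l_k in first-appearance
        order; the mapping is kept in ``level_labels``.
    raw_regressors:
        (n x q_k) matrix of the covariates whose coefficients vary randomly
        per level (e.g. a column of ones for a random intercept).
    """

    factor_vector: np.ndarray
    raw_regressors: np.ndarray
    level_labels: list = field(default_factory=list)

    def __post_init__(self):
        g, labels = _normalise_labels(self.factor_vector)
        self.factor_vector = g
        self.level_labels = labels
        z = np.atleast_2d(np.asarray(self.raw_regressors, dtype=np.float64))
        if z.shape[0] == 1 and g.shape[0] != 1:
            z = z.T
        if z.shape[0] != g.shape[0]:
            raise DesignError(
                f"raw_regressors has {z.shape[0]} rows, factor vector has "
                f"{g.shape[0]}"
            )
        if np.any(np.all(z == 0.0, axis=0)):
            raise DesignError("raw_regressors contains an all-zero column")
        self.raw_regressors = z

    @property
    def n_levels(self) -> int:
        return len(self.level_labels)

    @property
    def n_effects(self) -> int:
        return self.raw_regressors.shape[1]


@dataclass
class ModelSpec:
    """Full design: fixed-effects matrix plus ordered random-effects factors.

    ``r = 0`` (no factors) is accepted and denotes the ordinary linear model,
    used as the null model in random-effect likelihood-ratio tests.
    """

    fixed_design: np.ndarray
    factors: list[FactorSpec] = field(default_factory=list)

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.fixed_design, dtype=np.float64))
        if X.shape[1] == 0 or X.shape[0] == 0:
            raise DesignError("fixed design must have at least one row/column")
        self.fixed_design = X
        for k, f in enumerate(self.factors):
            if f.factor_vector.shape[0] != X.shape[0]:
                raise DesignError(
                    f"factor {k} has {f.factor_vector.shape[0]} rows, "
                    f"X has {X.shape[0]}"
                )

    @property
    def n(self) -> int:
        return self.fixed_design.shape[0]

    @property
    def p(self) -> int:
        return self.fixed_design.shape[1]

    @property
    def r(self) -> int:
        return len(self.factors)

    @property
    def q(self) -> int:
        return int(sum(f.n_levels * f.n_effects for f in self.factors))

    @property
    def level_counts(self) -> list[int]:
        return [f.n_levels for f in self.factors]

    @property
    def effect_counts(self) -> list[int]:
        return [f.n_effects for f in self.factors]

    def random_design(self) -> np.ndarray:
        if not self.factors:
            return np.zeros((self.n, 0))
        return build_random_design(self.factors)

    def factor_column_slices(self) -> list[slice]:
        """Column range of each factor's block inside Z."""
        out, start = [], 0
        for f in self.factors:
            width = f.n_levels * f.n_effects
            out.append(slice(start, start + width))
            start += width
        return out


@dataclass
class CovarianceBlocks:
    """Per-factor within-level covariance matrices D_k (q_k x q_k, symmetric).

    The implied full covariance is the direct sum over factors of
    ``I_{l_k} (x) D_k``, consistent with the level-major Z column ordering.
    """

    blocks: list[np.ndarray]

    def __post_init__(self):
        clean = []
        for k, Dk in enumerate(self.blocks):
            Dk = np.atleast_2d(np.asarray(Dk, dtype=np.float64))
            if Dk.shape[0] != Dk.shape[1]:
                raise DesignError(f"D_{k} is not square")
            if not np.allclose(Dk, Dk.T, atol=1e-10, rtol=0.0):
                raise DesignError(f"D_{k} is not symmetric")
            clean.append(Dk)
        self.blocks = clean


def build_indicator_matrix(g: np.ndarray, n_levels: int) -> np.ndarray:
    """(n x l) 0/1 indicator matrix: row i has a single 1 at column g[i]-1.

    Labels must already be dense integers in 1..n_levels and every level must
    occur at least once.
    """
    g = np.asarray(g, dtype=np.int64).ravel()
    bad = np.nonzero((g < 1) | (g > n_levels))[0]
    if bad.size:
        raise DesignError(
            f"factor label {g[bad[0]]} at row {bad[0]} outside 1..{n_levels}"
        )
    missing = set(range(1, n_levels + 1)) - set(g.tolist())
    if missing:
        raise DesignError(f"levels never observed: {sorted(missing)}")
    J = np.zeros((g.shape[0], n_levels), dtype=np.float64)
    J[np.arange(g.shape[0]), g - 1] = 1.0
    return J


def build_random_design(factors: list[FactorSpec]) -> np.ndarray:
    """Assemble Z by horizontally concatenating per-factor blocks.

    Row i of factor k's block is the Kronecker product of row i of the
    indicator matrix J_k with row i of the raw regressors z_k (the
    column-wise Khatri-Rao pairing of levels with effects), so the block is
    zero outside the columns of the observation's own level.
    """
    blocks = []
    for f in factors:
        J = build_indicator_matrix(f.factor_vector, f.n_levels)
        z = f.raw_regressors
        # row-wise Kronecker: (n, l, 1) * (n, 1, qk) -> level-major columns
        blk = (J[:, :, None] * z[:, None, :]).reshape(z.shape[0], -1)
        blocks.append(blk)
    if not blocks:
        return np.zeros((0, 0))
    return np.concatenate(blocks, axis=1)


def assemble_full_D(
    blocks: CovarianceBlocks | list[np.ndarray], level_counts: list[int]
) -> np.ndarray:
    """Full (q x q) block-diagonal D = direct sum over k of I_{l_k} (x) D_k."""
    if isinstance(blocks, CovarianceBlocks):
        blocks = blocks.blocks
    if len(blocks) != len(level_counts):
        raise DesignError("one level count required per covariance block")
    parts = []
    for Dk, lk in zip(blocks, level_counts):
        Dk = np.atleast_2d(np.asarray(Dk, dtype=np.float64))
        parts.append(np.kron(np.eye(lk), Dk))
    if not parts:
        return np.zeros((0, 0))
    q = sum(p.shape[0] for p in parts)
    D = np.zeros((q, q))
    start = 0
    for p in parts:
        w = p.shape[0]
        D[start : start + w, start : start + w] = p
        start += w
    return D


def _detect_sep(path) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    if "," in first:
        return ","
    if "\t" in first:
        return "\t"
    return r"\s+"


def load_design_matrix(path, header: bool = False) -> np.ndarray:
    """Read a delimited-text design matrix (CSV/TSV/whitespace)."""
    df = pd.read_csv(path, header=0 if header else None, sep=_detect_sep(path))
    return df.to_numpy(dtype=np.float64)


def load_factor_vector(path, header: bool = False) -> np.ndarray:
    """Read a single-column factor vector from delimited text."""
    df = pd.read_csv(path, header=0 if header else None, sep=_detect_sep(path))
    if df.shape[1] != 1:
        raise DesignError(f"{path}: factor vector must have one column")
    return df.iloc[:, 0].to_numpy()
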