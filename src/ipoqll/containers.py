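"""Core data containers for ordinal response data and GPCM parameters.

The response matrix holds integer category codes, 0-based per item, with
``-1`` marking a missing cell.  Item ``i`` with ``m_i + 1`` ordered
categories admits codes ``0..m_i``; different items may use different
numbers of categories (ragged thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1


class UnobservedCategoryError(ValueError):
    """Raised when an item never uses one of its interior categories.

    Joint maximum likelihood cannot estimate a threshold for a category
    that no subject chose; such items must be recoded first (see
    :func:`ipoqll.io.recode_categories`).
    """


@dataclass
class ResponseMatrix:
    """N subjects x P items of ordinal category codes.

    Parameters
    ----------
    values : ndarray of int, shape (N, P)
        Category codes ``0..m_i`` per item; ``-1`` for missing.
    n_categories : ndarray of int, shape (P,)
        Number of categories ``m_i + 1`` of each item (``>= 2``).
    subject_ids, item_ids : sequences of str
        Row and column labels, preserved through all reports.
    """

    values: np.ndarray
    n_categories: np.ndarray
    subject_ids: list = None
    item_ids: list = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (subjects x items) array")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValueError("need at least one subject and one item")
        self.n_categories = np.asarray(self.n_categories, dtype=np.int64)
        if self.n_categories.shape != (p,):
            raise ValueError("n_categories must have one entry per item")
        if np.any(self.n_categories < 2):
            raise ValueError("every item needs at least two categories (m_i >= 1)")
        if self.subject_ids is None:
            self.subject_ids = [f"s{i + 1}" for i in range(n)]
        if self.item_ids is None:
            self.item_ids = [f"item{i + 1}" for i in range(p)]
        self.subject_ids = list(map(str, self.subject_ids))
        self.item_ids = list(map(str, self.item_ids))
        if len(self.subject_ids) != n or len(self.item_ids) != p:
            raise ValueError("label lengths do not match the matrix shape")
        observed = self.values != MISSING
        if np.any(self.values[observed] < 0):
            raise ValueError("negative category codes other than -1 (missing)")
        too_high = observed & (self.values >= self.n_categories[None, :])
        if np.any(too_high):
            n_bad, i_bad = np.argwhere(too_high)[0]
            raise ValueError(
                f"response {self.values[n_bad, i_bad]} of subject "
                f"{self.subject_ids[n_bad]!r} on item {self.item_ids[i_bad]!r} "
                f"exceeds its maximum category {self.n_categories[i_bad] - 1}"
            )

    # -- basic shape helpers -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def m(self) -> np.ndarray:
        """Per-item threshold counts ``m_i`` (= n_categories - 1)."""
        return self.n_categories - 1

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing cells."""
        return self.values != MISSING

    def subset(self, items: Sequence[int]) -> "ResponseMatrix":
        """A new matrix containing only the given item columns (by index)."""
        items = list(items)
        return ResponseMatrix(
            self.values[:, items],
            self.n_categories[items],
            self.subject_ids,
            [self.item_ids[i] for i in items],
        )

    def check_category_coverage(self) -> None:
        """Raise :class:`UnobservedCategoryError` if any category is unused.

        Every code ``0..m_i`` of every item must occur at least once among
        the non-missing responses.
        """
        for i in range(self.n_items):
            col = self.values[:, i]
            used = np.unique(col[col != MISSING])
            expected = np.arange(self.n_categories[i])
            gap = np.setdiff1d(expected, used)
            if gap.size:
                raise UnobservedCategoryError(
                    f"item {self.item_ids[i]!r}: category {gap[0]} is never "
                    "observed; merge categories with recode_categories (CLI: "
                    "`ipoqll recode`) before fitting"
                )

    # -- conversion ----------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, one_based: bool = False, check_coverage: bool = True
    ) -> "ResponseMatrix":
        """Build from a subjects x items DataFrame (NaN = missing).

        With ``one_based=True`` codes ``1..m_i+1`` are shifted down to the
        internal 0-based convention.
        """
        arr = np.full(df.shape, MISSING, dtype=np.int64)
        for j, col in enumerate(df.columns):
            series = df[col]
            notna = series.notna().to_numpy()
            vals = series.to_numpy()[notna]
            as_int = np.asarray(vals, dtype=np.float64)
            if np.any(as_int != np.round(as_int)):
                bad = df.index[notna][np.argmax(as_int != np.round(as_int))]
                raise ValueError(
                    f"non-integer response in column {col!r}, row {bad!r}"
                )
            arr[notna, j] = as_int.astype(np.int64)
        if one_based:
            obs = arr != MISSING
            if np.any(arr[obs] < 1):
                raise ValueError("one_based declared but a 0 code is present")
            arr[obs] -= 1
        observed = arr != MISSING
        if not observed.any(axis=0).all():
            j = int(np.argmin(observed.any(axis=0)))
            raise ValueError(f"item {df.columns[j]!r} has no observed responses")
        n_cat = np.where(observed, arr, 0).max(axis=0) + 1
        n_cat = np.maximum(n_cat, 2)
        rm = cls(arr, n_cat, list(df.index), list(df.columns))
        if check_coverage:
            rm.check_category_coverage()
        return rm

    def to_dataframe(self) -> pd.DataFrame:
        """Subjects x items DataFrame with NaN for missing cells."""
        out = self.values.astype(float)
        out[self.values == MISSING] = np.nan
        return pd.DataFrame(out, index=self.subject_ids, columns=self.item_ids)


@dataclass
class GPCMParams:
    """Parameters of the generalized partial credit model.

    ``theta`` is the per-subject ability, ``beta`` the ragged per-item
    threshold lists (item i has m_i entries), and ``alpha`` the strictly
    positive per-item discrimination.  All on the logit scale.
    """

    theta: np.ndarray
    beta: list
    alpha: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.beta = [np.asarray(b, dtype=float).ravel() for b in self.beta]
        self.alpha = np.asarray(self.alpha, dtype=float)
        if len(self.beta) != self.alpha.shape[0]:
            raise ValueError("beta and alpha must describe the same items")
        finite = (
            np.all(np.isfinite(self.theta))
            and np.all(np.isfinite(self.alpha))
            and all(np.all(np.isfinite(b)) for b in self.beta)
        )
        if not finite:
            raise ValueError("non-finite GPCM parameter")
        if np.any(self.alpha <= 0):
            raise ValueError("discrimination parameters must be strictly positive")
        if any(b.size < 1 for b in self.beta):
            raise ValueError("every item needs at least one threshold")

    @property
    def n_items(self) -> int:
        return len(self.beta)

    @property
    def log_alpha(self) -> np.ndarray:
        return np.log(self.alpha)

    def restrict(self, items: Sequence[int]) -> "GPCMParams":
        items = list(items)
        return GPCMParams(
            self.theta, [self.beta[i] for i in items], self.alpha[items]
        )


@dataclass
class PenaltyConfig:
    """Ridge penalty weights of the penalized joint likelihood.

    ``lambda_theta`` weights the sum of squared abilities; ``lambda_in``
    and ``lambda_out`` weight the sum of squared log discriminations on
    the included and excluded itemsets.  The strong default on the
    included side (50) drives included-item discriminations towards 1
    (the partial credit model); the weak default on the excluded side
    (.05) lets excluded items absorb misfit via small discriminations.
    """

    lambda_theta: float = 0.05
    lambda_in: float = 50.0
    lambda_out: float = 0.05

    def __post_init__(self):
        for name in ("lambda_theta", "lambda_in", "lambda_out"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a nonnegative finite number")
            setattr(self, name, v)
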