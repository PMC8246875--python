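"""CSV reading/writing, category recoding and run configuration.

The response file dialect: a header row of item IDs, one row per
subject, integer category codes, empty cell = missing.  An optional
leading ``subject_id`` column carries row labels.  Files coded 1-based
are shifted to the internal 0-based convention when declared as such.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import MISSING, PenaltyConfig, ResponseMatrix

ID_COLUMN = "subject_id"


def read_responses(path, one_based: bool = False, id_col: str | None = None,
                   check_coverage: bool = True) -> ResponseMatrix:
    """Load a subjects x items CSV into a validated ResponseMatrix.

    ``id_col`` names the subject-label column; by default a column named
    ``subject_id`` is used when present.  Category-coverage violations
    (an interior code never observed) raise with a pointer to the recode
    utility.
    """
    df = pd.read_csv(path)
    if id_col is None and ID_COLUMN in df.columns:
        id_col = ID_COLUMN
    if id_col is not None:
        if id_col not in df.columns:
            raise ValueError(f"id column {id_col!r} not found in {path}")
        df = df.set_index(id_col)
    if df.shape[1] == 0:
        raise ValueError(f"no item columns in {path}")
    try:
        return ResponseMatrix.from_dataframe(df, one_based=one_based,
                                             check_coverage=check_coverage)
    except ValueError as err:
        raise type(err)(f"{path}: {err}") from err


def write_responses(responses: ResponseMatrix, path) -> None:
    """Write the CSV dialect read by :func:`read_responses` (0-based codes)."""
    df = responses.to_dataframe()
    out = df.astype("Int64")  # keeps integer codes, blanks for missing
    out.insert(0, ID_COLUMN, responses.subject_ids)
    out.to_csv(path, index=False)


def recode_categories(responses: ResponseMatrix, item, merge_map: dict) -> ResponseMatrix:
    """Merge response categories of one item.

    ``merge_map`` maps every old code of the item onto new codes that
    form a contiguous 0-based range (e.g. ``{0: 0, 1: 1, 2: 2, 3: 2}``
    merges the top two of four categories).  Counts are conserved; other
    items are untouched.  ``item`` is an item ID or a column index.
    """
    if isinstance(item, str):
        if item not in responses.item_ids:
            raise KeyError(f"unknown item {item!r}")
        j = responses.item_ids.index(item)
    else:
        j = int(item)
        if not (0 <= j < responses.n_items):
            raise IndexError("item index out of range")
    merge_map = {int(k): int(v) for k, v in merge_map.items()}
    targets = sorted(set(merge_map.values()))
    if targets != list(range(len(targets))):
        raise ValueError("merged codes must form a contiguous range 0..m'")
    old_codes = set(range(responses.n_categories[j]))
    if not old_codes <= set(merge_map):
        missing = sorted(old_codes - set(merge_map))
        raise ValueError(f"merge_map does not cover old code(s) {missing} "
                         f"of item {responses.item_ids[j]!r}")
    values = responses.values.copy()
    col = values[:, j]
    obs = col != MISSING
    col[obs] = np.array([merge_map[c] for c in col[obs]])
    n_cat = responses.n_categories.copy()
    n_cat[j] = len(targets)
    return ResponseMatrix(values, n_cat, responses.subject_ids, responses.item_ids)


@dataclass
class RunConfig:
    """All knobs of a run, serializable to YAML with round-trip equality."""

    penalties: PenaltyConfig = field(default_factory=PenaltyConfig)
    gtol: float = 1e-5
    ftol: float = 1e-9
    max_iter: int = 500
    min_size: int = 1
    exhaustive_limit: int = 20
    seed: int = 0
    n_jobs: int = 1
    one_based: bool = False
    output_dir: str = "."

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pen = d.pop("penalties", {})
        if isinstance(pen, dict):
            pen = PenaltyConfig(**pen)
        return cls(penalties=pen, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
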