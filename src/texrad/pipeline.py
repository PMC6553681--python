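"""Feature-table assembly and cleaning.

A feature table holds one row per subject and one column per
(sequence, tissue, feature) triple.  Cleaning removes columns with invalid
(non-finite) cells and near-zero-variance columns, recording the removal
reason per column; standardization to zero mean / unit variance is fit on
one table and applied to another so cross-validation folds never leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from texrad.features.extract import FeatureVector

#: Column-id separator: "<sequence>:<tissue>:<feature>".
SEP = ":"

#: Near-zero-variance defaults (most-common / second-most-common frequency
#: ratio, distinct-value percentage), as in the caret practice.
DEFAULT_NZV_FREQ_RATIO = 95.0 / 5.0
DEFAULT_NZV_UNIQUE_PCT = 10.0


class AssemblyError(ValueError):
    pass


class EmptyTableError(ValueError):
    pass


@dataclass
class FeatureTable:
    """Subjects x features matrix with labels and cleaning provenance."""

    data: pd.DataFrame
    labels: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise AssemblyError("duplicate subject ids")
        if self.data.columns.has_duplicates:
            raise AssemblyError("duplicate column ids")
        if not self.labels.index.equals(self.data.index):
            raise AssemblyError("labels index does not match table rows")
        if not set(self.labels.unique()) <= {0, 1}:
            raise AssemblyError("labels must be binary 0/1")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_rows(self, ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[ids].copy(), self.labels.loc[ids].copy(),
                            dict(self.provenance))


def column_id(sequence: str, tissue: str, feature: str) -> str:
    return f"{sequence}{SEP}{tissue}{SEP}{feature}"


def split_column_id(col: str) -> tuple[str, str, str]:
    sequence, tissue, feature = col.split(SEP, 2)
    return sequence, tissue, feature


def assemble_table(
    vectors: list[tuple[str, str, str, FeatureVector]],
    labels: dict[str, int],
) -> FeatureTable:
    """Build a table from (subject, sequence, tissue, FeatureVector) entries.

    Missing (subject, sequence, tissue) combinations become NaN cells;
    duplicate combinations and unlabelled subjects are errors.
    """
    if not vectors:
        raise AssemblyError("no feature vectors to assemble")
    cells: dict[str, dict[str, float]] = {}
    seen = set()
    for subject, sequence, tissue, fv in vectors:
        key = (subject, sequence, tissue)
        if key in seen:
            raise AssemblyError(f"duplicate (subject, sequence, tissue): {key}")
        seen.add(key)
        if subject not in labels:
            raise AssemblyError(f"subject {subject!r} has no label")
        row = cells.setdefault(subject, {})
        for name, value in fv.values.items():
            row[column_id(sequence, tissue, name)] = value
    data = pd.DataFrame.from_dict(cells, orient="index").sort_index()
    data = data[sorted(data.columns)]
    lab = pd.Series({s: int(labels[s]) for s in data.index}, name="label").loc[data.index]
    return FeatureTable(data=data, labels=lab)


def _near_zero_variance(col: np.ndarray, freq_ratio: float, unique_pct: float) -> bool:
    values, counts = np.unique(col, return_counts=True)
    if len(values) == 1:
        return True  # zero variance
    counts = np.sort(counts)[::-1]
    ratio = counts[0] / counts[1]
    pct_unique = 100.0 * len(values) / len(col)
    return ratio > freq_ratio and pct_unique < unique_pct


def clean_table(
    table: FeatureTable,
    nzv_freq_ratio: float = DEFAULT_NZV_FREQ_RATIO,
    nzv_unique_pct: float = DEFAULT_NZV_UNIQUE_PCT,
) -> FeatureTable:
    """Drop invalid and (near-)zero-variance columns, recording reasons.

    Idempotent; raises :class:`EmptyTableError` when nothing survives.
    """
    provenance = dict(table.provenance)
    keep = []
    for col in table.data.columns:
        values = table.data[col].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            provenance[col] = "invalid"
        elif _near_zero_variance(values, nzv_freq_ratio, nzv_unique_pct):
            provenance[col] = "near_zero_variance"
        else:
            provenance[col] = "none"
            keep.append(col)
    if not keep:
        raise EmptyTableError("cleaning removed every column")
    return FeatureTable(table.data[keep].copy(), table.labels.copy(), provenance)


def standardize(
    train: FeatureTable,
    apply_to: FeatureTable | None = None,
    on_zero_sd: str = "error",
) -> tuple[FeatureTable, FeatureTable | None, pd.DataFrame]:
    """Zero-mean / unit-variance transform fit on ``train`` only.

    Uses the sample standard deviation (n-1 denominator).  ``apply_to`` is
    transformed with the *train* statistics.  Returns the transformed
    tables plus the per-column (mean, sd) parameters.

    ``on_zero_sd``: a cleaned table should have no constant column, so the
    default is to raise; ``"unit"`` scales such columns by 1 instead (they
    become all-zero), which cross-validation uses for columns that happen
    to be constant within one training fold.
    """
    if on_zero_sd not in ("error", "unit"):
        raise ValueError("on_zero_sd must be 'error' or 'unit'")
    means = train.data.mean(axis=0)
    sds = train.data.std(axis=0, ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        if on_zero_sd == "error":
            raise ValueError(
                f"zero-SD columns reached standardization: {list(zero.index)[:5]}")
        sds = sds.mask(sds == 0, 1.0)
    params = pd.DataFrame({"mean": means, "sd": sds})
    out_train = replace(train, data=(train.data - means) / sds)
    out_apply = None
    if apply_to is not None:
        if list(apply_to.data.columns) != list(train.data.columns):
            raise ValueError("apply_to columns differ from train columns")
        out_apply = replace(apply_to, data=(apply_to.data - means) / sds)
    return out_train, out_apply, params
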