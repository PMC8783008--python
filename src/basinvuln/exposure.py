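"""Exposure accounting: extensive social-ecological totals per category.

Given per-basin category labels (stress/trend combinations, vulnerability
classes, ...) and per-basin extensive variables (population, crop
production, GDP, wetland counts), report the sum within each category and
its share of the global total. Over an exhaustive partition the shares sum
to 1 per variable; unlabeled basins are rolled into a residual category so
the partition is always exhaustive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RESIDUAL_LABEL = "(unlabeled)"


def exposure_by_category(
    extensives: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Long-format exposure summary: category x variable -> value, share.

    ``extensives`` is indexed by basin id with one column per extensive
    variable; ``labels`` maps the same basins to category labels (NaN/None
    allowed, reported under the residual category). Shares are relative to
    the global total over all listed basins, so shares per variable sum to 1
    whenever the variable's total is nonzero.
    """
    if not extensives.index.equals(labels.reindex(extensives.index).index):
        raise ValueError("extensives and labels must cover the same basins")
    lab = labels.reindex(extensives.index)
    lab = lab.where(lab.notna() & (lab != ""), RESIDUAL_LABEL).astype(str)
    totals = extensives.sum(axis=0)
    grouped = extensives.groupby(lab).sum()
    records = []
    for category, row in grouped.iterrows():
        for variable, value in row.items():
            total = totals[variable]
            share = float(value / total) if total != 0 else np.nan
            records.append(
                {
                    "category": category,
                    "variable": variable,
                    "value": float(value),
                    "share": share,
                }
            )
    return pd.DataFrame.from_records(records)


def adaptability_status_crosstab(
    B: pd.Series,
    A: pd.Series,
    a_breaks: tuple[float, ...] = (1 / 3, 2 / 3),
    b_breaks: tuple[float, ...] = (1 / 3, 2 / 3),
) -> pd.DataFrame:
    """Basin counts per adaptability class x freshwater-status class.

    Classes are formed by cutting A and B at the given interior break
    points (defaults: terciles of the unit interval; both indicators live in
    [0,1]). Rows are adaptability classes (low..high), columns are status
    classes; unscorable basins (NaN in either) are excluded. Counts sum to
    the number of scorable basins.
    """
    a_breaks = tuple(sorted(a_breaks))
    b_breaks = tuple(sorted(b_breaks))
    ok = B.notna() & A.notna()
    a_bins = np.digitize(A[ok].to_numpy(dtype=float), a_breaks)
    b_bins = np.digitize(B[ok].to_numpy(dtype=float), b_breaks)

    def _names(breaks: tuple[float, ...]) -> list[str]:
        n = len(breaks) + 1
        if n == 3:
            return ["low", "moderate", "high"]
        return [f"class {i + 1}" for i in range(n)]

    rows = _names(a_breaks)
    cols = _names(b_breaks)
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    np.add.at(counts, (a_bins, b_bins), 1)
    return pd.DataFrame(
        counts,
        index=pd.Index(rows, name="adaptability"),
        columns=pd.Index(cols, name="status"),
    )
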