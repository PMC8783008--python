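"""National IWRM scores joined to basins; IWRM-versus-vulnerability views.

IWRM (integrated water resources management) implementation is tracked as a
national 0-100 score (SDG 6.5.1). Basins inherit the overlap-area-weighted
mean of the scores of the nations they intersect; basins intersecting two
or more nations are transboundary. The comparison view places basins in
quadrants of (vulnerability, IWRM) and contrasts mean IWRM between
transboundary and non-transboundary hotspot basins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

QUADRANT_LABELS = {
    1: "high-IWRM/low-V",
    2: "low-IWRM/low-V",
    3: "low-IWRM/high-V",
    4: "high-IWRM/high-V",
}


def basin_iwrm_score(
    overlaps: pd.DataFrame, national_scores: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Overlap-area-weighted national IWRM score per basin.

    ``overlaps`` is long-format (basin_id, nation_id, fraction) as produced
    by :func:`basinvuln.grid.nation_overlap_fractions`; ``national_scores``
    maps nation_id -> score in [0, 100]. A basin touching a nation with no
    score is flagged missing (NaN score), never silently renormalized.
    Returns a frame indexed by basin_id with columns iwrm_score, n_nations,
    transboundary.
    """
    if isinstance(national_scores, pd.DataFrame):
        scores = national_scores.set_index("nation_id")["iwrm_score"]
    else:
        scores = national_scores
    fin = scores.dropna()
    if ((fin < 0) | (fin > 100)).any():
        raise ValueError("IWRM scores must lie in [0, 100]")
    df = overlaps.copy()
    df["score"] = df["nation_id"].map(scores)

    def _one(g: pd.DataFrame) -> pd.Series:
        if g["score"].isna().any():
            score = np.nan
        else:
            score = float(np.sum(g["score"] * g["fraction"]) / np.sum(g["fraction"]))
        n = int(g["nation_id"].nunique())
        return pd.Series(
            {"iwrm_score": score, "n_nations": n, "transboundary": n >= 2}
        )

    out = df.groupby("basin_id").apply(_one, include_groups=False)
    out["n_nations"] = out["n_nations"].astype(int)
    out["transboundary"] = out["transboundary"].astype(bool)
    out.index.name = "basin_id"
    return out


@dataclass(frozen=True)
class IwrmSummary:
    """Quadrant assignment and hotspot IWRM contrasts."""

    table: pd.DataFrame  # per basin: iwrm_score, V, hotspot, quadrant, ...
    quadrant_counts: pd.Series
    mean_iwrm_transboundary_hotspots: float
    mean_iwrm_nontransboundary_hotspots: float
    share_hotspots_transboundary: float


def iwrm_vulnerability_summary(
    iwrm_table: pd.DataFrame,
    vuln_table: pd.DataFrame,
    iwrm_split: float = 50.0,
    v_split: float | None = None,
) -> IwrmSummary:
    """Cross basin IWRM implementation with vulnerability.

    ``v_split`` sets the vulnerability split for the quadrants; if None, the
    hotspot flag (classification-based) defines "high vulnerability".
    Group means over an empty hotspot set are reported as NaN, not zero.
    """
    joined = iwrm_table.join(vuln_table[["V", "hotspot"]], how="inner")
    if len(joined) != len(iwrm_table) or len(joined) != len(vuln_table):
        raise ValueError("IWRM and vulnerability tables must cover the same basins")
    v = joined["V"].to_numpy(dtype=float)
    if v_split is None:
        high_v = joined["hotspot"].to_numpy(dtype=bool)
    else:
        fin = v[np.isfinite(v)]
        if fin.size and (v_split < fin.min() or v_split > fin.max()):
            import warnings

            warnings.warn("v_split lies outside the data range", stacklevel=2)
        high_v = v > v_split
    score = joined["iwrm_score"].to_numpy(dtype=float)
    fin_s = score[np.isfinite(score)]
    if fin_s.size and (iwrm_split < fin_s.min() or iwrm_split > fin_s.max()):
        import warnings

        warnings.warn("iwrm_split lies outside the data range", stacklevel=2)
    high_iwrm = score >= iwrm_split
    quadrant = np.where(
        high_v,
        np.where(high_iwrm, 4, 3),
        np.where(high_iwrm, 1, 2),
    )
    joined = joined.assign(
        quadrant=quadrant,
        quadrant_label=[QUADRANT_LABELS[q] for q in quadrant],
    )
    hotspots = joined[joined["hotspot"]]
    tb = hotspots[hotspots["transboundary"]]
    ntb = hotspots[~hotspots["transboundary"]]
    return IwrmSummary(
        table=joined,
        quadrant_counts=joined["quadrant"].value_counts().sort_index(),
        mean_iwrm_transboundary_hotspots=float(tb["iwrm_score"].mean())
        if len(tb)
        else float("nan"),
        mean_iwrm_nontransboundary_hotspots=float(ntb["iwrm_score"].mean())
        if len(ntb)
        else float("nan"),
        share_hotspots_transboundary=float(hotspots["transboundary"].mean())
        if len(hotspots)
        else float("nan"),
    )
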