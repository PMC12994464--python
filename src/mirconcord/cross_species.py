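"""Combined-evidence concordance screening across two species.

Homologous features (here: human mature miRNAs paired with zebrafish
pre-miRNAs) are tested for shared dysregulation by Fisher's product method:
the two per-species raw p-values are combined into chi2 = -2*sum(ln p_i)
with 2k degrees of freedom (k = 2 tests), the combined p-values are BH
adjusted across all evaluated pairs, and a pair is called when its adjusted
combined p is below alpha AND the two log2 fold-changes share a sign
(directional concordance).  Within-species paralogs (e.g. dre-miR-21-1/-2
mapping to one human miR-21) are first collapsed to one representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .de_io import DETable, bh_adjust

#: floor applied to underflowed p-values before taking logs
P_FLOOR = 1e-300

PARALOG_POLICIES = ("min_p", "within_species_fisher")


def fisher_combine(p_values) -> tuple[float, int, float]:
    """Fisher's product method for k independent p-values.

    Returns ``(chi2, df, p_combined)`` with ``chi2 = -2 * sum(ln p_i)``,
    ``df = 2k`` and ``p_combined`` the upper-tail chi-square probability.
    Zero p-values (DE-software underflow) are clamped to 1e-300 with a
    warning so the statistic stays finite and ordering is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1] (0 is clamped)")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to 1e-300 before log", RuntimeWarning)
        p = np.maximum(p, P_FLOOR)
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclass
class HomologyMap:
    """Pairs of (species-A id, species-B id); many-to-many permitted."""

    pairs: pd.DataFrame  # columns: human_id, fish_id

    def __post_init__(self) -> None:
        df = self.pairs
        if list(df.columns[:2]) != ["human_id", "fish_id"]:
            df = df.iloc[:, :2].set_axis(["human_id", "fish_id"], axis=1)
        df = df.astype(str)
        if (df["human_id"].str.len() == 0).any() or (df["fish_id"].str.len() == 0).any():
            raise ValueError("empty id in homology map")
        if df.duplicated().any():
            raise ValueError("duplicate pairs in homology map")
        self.pairs = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)


def read_homology_map(path: str | Path) -> HomologyMap:
    """Two-column delimited file: species-A id, species-B id."""
    df = pd.read_csv(path, sep=None, engine="python", header=0)
    return HomologyMap(df)


def collapse_paralogs(
    fish_table: DETable,
    homology: HomologyMap,
    policy: str = "min_p",
) -> tuple[pd.DataFrame, int]:
    """Reduce many-to-one paralog mappings to one fish record per human id.

    ``min_p`` keeps the paralog with the smallest raw p (ties broken by
    lexicographically smallest id) and carries its L2FC.  The
    ``within_species_fisher`` policy instead combines the paralog p-values
    by the product method and takes the direction (L2FC) of the smallest-p
    paralog.  Pairs whose fish feature is absent from the table are dropped
    with a warning; the count of dropped pairs is returned.

    Returns ``(frame, n_dropped)`` where the frame has columns
    ``human_id, fish_id, l2fc, pvalue, n_paralogs``.
    """
    if policy not in PARALOG_POLICIES:
        raise ValueError(f"unknown paralog policy {policy!r}")
    merged = homology.pairs.merge(
        fish_table.df, left_on="fish_id", right_on="feature_id", how="left"
    )
    present = merged["feature_id"].notna() & (merged["tested"] == True)  # noqa: E712
    n_dropped = int((~present).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} homology pair(s) dropped: fish feature absent or untested",
            RuntimeWarning,
        )
    merged = merged[present]
    # smallest p first, ties broken lexicographically by fish id
    merged = merged.sort_values(["human_id", "pvalue", "fish_id"], kind="stable")
    rep = merged.drop_duplicates("human_id", keep="first").set_index("human_id")
    sizes = merged.groupby("human_id").size()
    if policy == "within_species_fisher":
        # product method within species; for a single paralog this is the
        # identity (sf(-2 ln p, 2) == p)
        logp = np.log(np.maximum(merged["pvalue"].to_numpy(dtype=float), P_FLOOR))
        chi2 = -2.0 * pd.Series(logp, index=merged["human_id"].values).groupby(level=0).sum()
        pval = pd.Series(stats.chi2.sf(chi2.to_numpy(), 2 * sizes.loc[chi2.index].to_numpy()),
                         index=chi2.index)
    else:
        pval = rep["pvalue"]
    out = pd.DataFrame(
        {
            "human_id": rep.index,
            "fish_id": rep["fish_id"].to_numpy(),
            "l2fc": rep["log2FoldChange"].to_numpy(dtype=float),
            "pvalue": pval.loc[rep.index].to_numpy(dtype=float),
            "n_paralogs": sizes.loc[rep.index].to_numpy(dtype=int),
        }
    ).sort_values("human_id", kind="stable").reset_index(drop=True)
    return out, n_dropped


def concordance_screen(
    human: DETable,
    fish: DETable,
    homology: HomologyMap,
    alpha: float = 0.05,
    paralog_policy: str = "min_p",
) -> tuple[pd.DataFrame, dict]:
    """Screen homolog pairs for concordant cross-species dysregulation.

    For every pair mappable into both tables, combine the human and fish raw
    p-values (k=2, df=4), BH-adjust the combined p across exactly the
    evaluated pairs, and call a pair when ``q_combined <= alpha`` and the two
    L2FCs share a sign (a zero L2FC is never concordant).

    Returns the per-pair evidence frame (one row per human id, columns
    ``pair_id, fish_id, p_human, p_fish, l2fc_human, l2fc_fish, chi2, df,
    p_combined, q_combined, concordant, called, direction``) and a summary
    dict with evaluated/called/up/down counts.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    collapsed, n_dropped = collapse_paralogs(fish, homology, paralog_policy)
    joined = collapsed.merge(
        human.df, left_on="human_id", right_on="feature_id", how="inner"
    )
    joined = joined[joined["tested"].astype(bool)]
    n_dropped += len(collapsed) - len(joined)
    if joined.empty:
        raise ValueError("no homolog pair present in both DE tables")
    p_h = joined["pvalue_y"].to_numpy(dtype=float)
    p_f = joined["pvalue_x"].to_numpy(dtype=float)
    if np.any(p_h == 0) or np.any(p_f == 0):
        warnings.warn("p-value of 0 clamped to 1e-300 before log", RuntimeWarning)
    chi2 = -2.0 * (np.log(np.maximum(p_h, P_FLOOR)) + np.log(np.maximum(p_f, P_FLOOR)))
    ev = pd.DataFrame(
        {
            "pair_id": joined["human_id"].to_numpy(),
            "fish_id": joined["fish_id"].to_numpy(),
            "p_human": p_h,
            "p_fish": p_f,
            "l2fc_human": joined["log2FoldChange"].to_numpy(dtype=float),
            "l2fc_fish": joined["l2fc"].to_numpy(dtype=float),
            "chi2": chi2,
            "df": 4,
            "p_combined": stats.chi2.sf(chi2, 4),
        }
    ).sort_values("pair_id", kind="stable").reset_index(drop=True)
    ev["q_combined"] = bh_adjust(ev["p_combined"].to_numpy())
    sh = np.sign(ev["l2fc_human"].to_numpy())
    sf = np.sign(ev["l2fc_fish"].to_numpy())
    ev["concordant"] = (sh == sf) & (sh != 0)
    ev["called"] = (ev["q_combined"] <= alpha) & ev["concordant"]
    ev["direction"] = np.where(
        ev["called"] & (sh > 0), "up", np.where(ev["called"] & (sh < 0), "down", "none")
    )
    summary = {
        "n_pairs_evaluated": int(len(ev)),
        "n_pairs_dropped": int(n_dropped),
        "n_called": int(ev["called"].sum()),
        "n_up": int((ev["direction"] == "up").sum()),
        "n_down": int((ev["direction"] == "down").sum()),
        "alpha": alpha,
        "paralog_policy": paralog_policy,
    }
    return ev, summary
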