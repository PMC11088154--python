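"""Probe-performance classification and pool rebalancing.

Under equimolar pooling every probe should capture the same share of the
run's deduplicated reads: 1/n_probes (0.001 at one significant figure for a
903-probe pool).  Probes whose read proportion falls below a lower cutoff
(1e-4) or whose absolute deduplicated count is under 30 are boosted 10-fold
in the phosphorylated pool; probes above the upper cutoff (1e-2) receive an
equimolar dose of unphosphorylated competitor, which hybridizes but cannot
be extended/ligated and so suppresses their capture.
"""

from __future__ import annotations

import json

import pandas as pd

from .panel import PanelError

CATEGORIES = ("under", "optimal", "over")


def expected_proportion(panel_size: int) -> tuple[float, float]:
    """Optimum per-probe read share for an equimolar pool.

    Returns ``(exact, rounded)`` where ``rounded`` is the one-significant-
    figure value used in report text (903 probes -> 1/903 ~ 0.0011, reported
    as 0.001)."""
    if panel_size < 1:
        raise PanelError("panel_size must be >= 1")
    exact = 1.0 / panel_size
    rounded = float(f"{exact:.1g}")
    return exact, rounded


def performance_from_coverage(coverage: pd.DataFrame, on: str = "dedup") -> pd.DataFrame:
    """Add per-probe read proportions (share of the run total) to a coverage
    table.  Proportions are computed on deduplicated reads by default."""
    df = coverage.copy()
    total = df[on].sum()
    df["proportion"] = df[on] / total if total > 0 else 0.0
    return df


def classify(perf: pd.DataFrame, low_cut: float = 1e-4, high_cut: float = 1e-2,
             min_reads: int = 30) -> pd.DataFrame:
    """Categorize probes as under / optimal / over performing.

    A probe is *under* when its proportion is below ``low_cut`` OR its
    deduplicated count is strictly below ``min_reads`` (either signal alone
    triggers a boost); *over* when the proportion exceeds ``high_cut``;
    otherwise *optimal*.  Monotone in proportion: raising a probe's
    proportion never moves it toward "under".
    """
    df = perf.copy()

    def cat(row):
        if row["proportion"] < low_cut or row["dedup"] < min_reads:
            return "under"
        if row["proportion"] > high_cut:
            return "over"
        return "optimal"

    df["category"] = df.apply(cat, axis=1)
    return df


def make_plan(categorized: pd.DataFrame, base_conc_uM: float = 0.1,
              boost: float = 10.0) -> pd.DataFrame:
    """Pooling recipe from categories.

    under   -> phosphorylated concentration boosted ``boost`` x base;
    over    -> equimolar unphosphorylated competitor added, phosphorylated
               dose unchanged;
    optimal -> unchanged.
    """
    if "category" not in categorized.columns:
        raise PanelError("run classify() before make_plan()")
    rows = []
    for _, r in categorized.iterrows():
        cat = r["category"]
        phos = base_conc_uM * boost if cat == "under" else base_conc_uM
        unphos = base_conc_uM if cat == "over" else 0.0
        rows.append({"probe_id": r["probe_id"], "category": cat,
                     "phos_uM": phos, "unphos_uM": unphos})
    return pd.DataFrame(rows, columns=["probe_id", "category", "phos_uM", "unphos_uM"])


def rebalance(coverage: pd.DataFrame, base_conc_uM: float = 0.1,
              boost: float = 10.0, low_cut: float = 1e-4,
              high_cut: float = 1e-2, min_reads: int = 30,
              on: str = "dedup") -> pd.DataFrame:
    """One-call pipeline: proportions -> categories -> plan."""
    return make_plan(classify(performance_from_coverage(coverage, on=on),
                              low_cut=low_cut, high_cut=high_cut,
                              min_reads=min_reads),
                     base_conc_uM=base_conc_uM, boost=boost)


def write_plan(plan: pd.DataFrame, path, summary_path=None) -> None:
    plan.to_csv(path, sep="\t", index=False)
    if summary_path is not None:
        counts = plan["category"].value_counts().to_dict()
        with open(summary_path, "w") as fh:
            json.dump({c: int(counts.get(c, 0)) for c in CATEGORIES},
                      fh, indent=1, sort_keys=True)


def read_plan(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
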