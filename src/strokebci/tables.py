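"""Packaged accuracy tables of the stroke/healthy BCI study.

The original EEG recordings were never deposited; what the study published
are accuracy tables and a feature-band table.  Those printed values are
shipped here as CSV fixtures so the group statistics can be recomputed:

- ``table5``: cross-dataset accuracies, one individual BCI per healthy
  training dataset (columns H1-H10) applied to every other dataset (rows);
  self-train cells are empty.
- ``table6``: grouped-healthy BCI tested on each stroke dataset.
- ``table7``: leave-one-out over the healthy datasets.
- ``table8``: longitudinal (early-trained, late-tested) stroke accuracies.
- ``table10``: frequency range (Hz) of the four top-ranked CSP features
  per dataset.

Dataset ids encode the group: H* healthy, S*E early stroke, S*L late
stroke.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .stats import rank_sum, summarize_accuracies

__all__ = ["load_table", "dataset_group", "table5_groups",
           "reproduce_printed_stats"]

_TABLES = ("table5", "table6", "table7", "table8", "table10")


def load_table(name: str) -> pd.DataFrame:
    if name not in _TABLES:
        raise ValueError(f"unknown table {name!r}; available: {_TABLES}")
    ref = resources.files("strokebci") / "tables" / f"{name}.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def dataset_group(dataset_id: str) -> str:
    if dataset_id.startswith("H"):
        return "healthy"
    if dataset_id.startswith("S") and dataset_id.endswith("E"):
        return "stroke_early"
    if dataset_id.startswith("S") and dataset_id.endswith("L"):
        return "stroke_late"
    raise ValueError(f"cannot infer group of dataset id {dataset_id!r}")


def table5_groups() -> dict[str, np.ndarray]:
    """Cross-dataset accuracy cells of table5, grouped by test dataset.

    healthy = the 90 off-diagonal healthy-test cells; stroke groups are all
    50 early- and 50 late-test cells.
    """
    t5 = load_table("table5").set_index("test")
    cells = {g: [] for g in ("healthy", "stroke_early", "stroke_late")}
    for ds, row in t5.iterrows():
        cells[dataset_group(ds)].extend(row.dropna().tolist())
    out = {g: np.array(v) for g, v in cells.items()}
    out["all_stroke"] = np.concatenate([out["stroke_early"], out["stroke_late"]])
    return out


def reproduce_printed_stats() -> dict:
    """Recompute every published summary statistic from the table fixtures.

    Returns a flat dict: per-group medians/means/SDs of the table-5 cells,
    the rank-sum |Z| and effect sizes r between groups, the grouped /
    leave-one-out / longitudinal averages of tables 6-8, and the modal
    frequency-range count of the healthy rows of table 10.
    """
    out: dict[str, float] = {}
    groups = table5_groups()
    for key, vals in groups.items():
        s = summarize_accuracies(vals)
        out[f"table5_{key}_median"] = s["median"]
        out[f"table5_{key}_mean"] = s["mean"]
        out[f"table5_{key}_sd"] = s["sd"]
    for name, (a, b) in {
        "healthy_vs_all_stroke": (groups["healthy"], groups["all_stroke"]),
        "healthy_vs_early": (groups["healthy"], groups["stroke_early"]),
        "healthy_vs_late": (groups["healthy"], groups["stroke_late"]),
        "early_vs_late": (groups["stroke_early"], groups["stroke_late"]),
    }.items():
        rs = rank_sum(a, b)
        out[f"table5_{name}_absZ"] = rs["Z"]
        out[f"table5_{name}_r"] = rs["r"]

    t6 = load_table("table6").set_index("test")["accuracy"]
    out["table6_all_mean"] = float(t6.mean())
    out["table6_all_sd"] = float(t6.std(ddof=1))
    early = t6[[i for i in t6.index if i.endswith("E")]]
    late = t6[[i for i in t6.index if i.endswith("L")]]
    out["table6_early_mean"] = float(early.mean())
    out["table6_early_sd"] = float(early.std(ddof=1))
    out["table6_late_mean"] = float(late.mean())
    out["table6_late_sd"] = float(late.std(ddof=1))
    out["table6_all_median"] = float(t6.median())

    t7 = load_table("table7")["accuracy"]
    out["table7_mean"] = float(t7.mean())
    out["table7_sd"] = float(t7.std(ddof=1))
    out["table7_median"] = float(t7.median())
    rs = rank_sum(t7.to_numpy(), t6.to_numpy())
    out["grouped_healthy_vs_stroke_absZ"] = rs["Z"]
    out["grouped_healthy_vs_stroke_r"] = rs["r"]

    t8 = load_table("table8")["accuracy"]
    out["table8_mean"] = float(t8.mean())
    out["table8_sd"] = float(t8.std(ddof=1))
    out["table8_median"] = float(t8.median())

    t10 = load_table("table10").set_index("dataset")
    healthy_rows = t10.loc[[i for i in t10.index if i.startswith("H")]]
    out["table10_healthy_16_20_count"] = float(
        (healthy_rows.to_numpy() == "16-20").sum())
    return out
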