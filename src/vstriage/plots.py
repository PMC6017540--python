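"""The six hit-selection plots: four property histograms and the two LEI planes.

Every plot function returns the matplotlib figure *and* the numeric series
behind it, and the writers save both (PNG + TSV), so downstream checks and
re-plots work on numbers rather than pixels.

SEI–BEI plane
    Scatter of (SEI, BEI).  Compounds with the same PSA/MW ratio *r* lie on
    the origin line BEI = 10·r·SEI, so a family of reference ratio lines
    partitions the plane into drug-likeness regions: high ratios
    (0.753–0.320) are poor space, ~0.200 acceptable, 0.150–0.090 good.

NSEI–nBEI plane
    Scatter of (NSEI, nBEI).  Since nBEI = NPOL·NSEI + log10 NHEA, compounds
    sharing an NPOL value fall near a diagonal of slope NPOL (exactly on it
    when NHEA is constant); the plot draws one labelled guide line per NPOL
    group, fitting the intercept as the group's mean log10 NHEA.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .efficiency import DEFAULT_GRADIENTS, GOOD_CUT, POOR_CUT

HISTOGRAM_PARAMETERS = ("PSA", "MW", "cLogP", "HBA")

#: Default two-group scatter colours: group 1 red, group 2 blue.
GROUP_COLOURS = ("tab:red", "tab:blue")


def _band_colour(r: float) -> str:
    if r > POOR_CUT:
        return "red"
    if r > GOOD_CUT:
        return "gold"
    return "green"


def plot_sei_bei(
    rows: pd.DataFrame,
    gradients: Sequence[float] = DEFAULT_GRADIENTS,
    group_labels: pd.Series | dict | None = None,
) -> tuple[plt.Figure, pd.DataFrame]:
    """SEI–BEI scatter with PSA/MW ratio reference lines.

    Each gradient ``r`` is drawn as the line ``BEI = 10·r·SEI`` through the
    origin, coloured by its drug-likeness band.  Rows with undefined SEI or
    BEI are dropped (with a warning when nothing is left).  ``group_labels``
    maps ligand id → group for two-group colouring (e.g. two site clusters).
    """
    series = rows[["SEI", "BEI"]].dropna().copy()
    fig, ax = plt.subplots(figsize=(6, 5))
    if series.empty:
        import warnings

        warnings.warn("no rows with defined SEI and BEI; empty figure", stacklevel=2)
    if group_labels is not None:
        labels = pd.Series(group_labels)
        series["group"] = labels.reindex(series.index)
        for colour, (name, grp) in zip(GROUP_COLOURS, series.groupby("group", sort=True)):
            ax.scatter(grp["SEI"], grp["BEI"], s=12, color=colour, label=str(name))
        ax.legend(title="group", fontsize=8)
    else:
        ax.scatter(series["SEI"], series["BEI"], s=12, color="tab:blue")
    xmax = max(float(series["SEI"].max()) if len(series) else 1.0, 1.0) * 1.1
    for r in gradients:
        xs = np.array([0.0, xmax])
        ax.plot(xs, 10.0 * r * xs, color=_band_colour(r), lw=1, alpha=0.8)
        ax.annotate(f"{r:.3f}", (xmax, 10.0 * r * xmax), fontsize=7)
    ax.set_xlabel("SEI  (pKi per 100 Å² PSA)")
    ax.set_ylabel("BEI  (pKi per kDa)")
    ax.set_xlim(left=0)
    ax.set_ylim(bottom=0)
    ax.set_title("SEI–BEI efficiency plane")
    return fig, series


def plot_nsei_nbei(
    rows: pd.DataFrame, group_labels: pd.Series | dict | None = None
) -> tuple[plt.Figure, pd.DataFrame]:
    """NSEI–nBEI scatter with one labelled guide diagonal per NPOL value.

    Requires NPOL > 0 rows (NSEI defined).  The guide for NPOL = k is
    ``nBEI = k·NSEI + c`` with the intercept fitted as the group mean of
    ``nBEI − k·NSEI`` (= mean log10 NHEA), an exact line when NHEA is
    constant within the group.
    """
    cols = ["NSEI", "nBEI"]
    series = rows[cols].dropna().copy()
    # NPOL recovered from the identities: pKi = NSEI·NPOL, so NPOL = pKi/NSEI;
    # carried explicitly when present
    if "HBA" in rows.columns:
        series["NPOL"] = rows.loc[series.index, "HBA"].astype(int)  # HBA ≡ N+O count
    fig, ax = plt.subplots(figsize=(6, 5))
    if series.empty:
        import warnings

        warnings.warn("no rows with defined NSEI and nBEI; empty figure", stacklevel=2)
    if group_labels is not None:
        labels = pd.Series(group_labels)
        series["group"] = labels.reindex(series.index)
        for colour, (name, grp) in zip(GROUP_COLOURS, series.groupby("group", sort=True)):
            ax.scatter(grp["NSEI"], grp["nBEI"], s=12, color=colour, label=str(name))
        ax.legend(title="group", fontsize=8)
    else:
        ax.scatter(series["NSEI"], series["nBEI"], s=12, color="tab:blue")
    if "NPOL" in series.columns and len(series):
        xmax = float(series["NSEI"].max()) * 1.1
        for npol, grp in series.groupby("NPOL"):
            c = float((grp["nBEI"] - npol * grp["NSEI"]).mean())
            xs = np.array([0.0, xmax])
            ax.plot(xs, npol * xs + c, lw=0.8, color="grey", alpha=0.7)
            ax.annotate(str(int(npol)), (xmax, npol * xmax + c), fontsize=7)
    ax.set_xlabel("NSEI  (pKi per polar atom)")
    ax.set_ylabel("nBEI  (−log10(Ki/NHEA))")
    ax.set_title("NSEI–nBEI efficiency plane")
    return fig, series


def plot_histogram(
    rows: pd.DataFrame, parameter: str, bins: int | str | Sequence[float] = "fd"
) -> tuple[plt.Figure, pd.DataFrame]:
    """Histogram of one summary parameter; counts always sum to the number of
    rows with a defined value.  Default binning is Freedman–Diaconis."""
    if parameter not in rows.columns:
        raise ValueError(f"unknown parameter {parameter!r}")
    values = rows[parameter].dropna().to_numpy(dtype=float)
    if len(values) and np.ptp(values) == 0:
        bins = 1  # all-equal values: one occupied bin
    counts, edges = np.histogram(values, bins=bins) if len(values) else (np.zeros(1, int), np.array([0.0, 1.0]))
    series = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", edgecolor="black")
    ax.set_xlabel(parameter)
    ax.set_ylabel("number of compounds")
    ax.set_title(f"{parameter} distribution")
    return fig, series


def _save(fig: plt.Figure, series: pd.DataFrame, out_dir: Path, name: str) -> None:
    fig.savefig(out_dir / f"{name}.png", dpi=120)
    series.to_csv(out_dir / f"{name}.tsv", sep="\t")
    plt.close(fig)


def plot_bundle(
    rows: pd.DataFrame,
    out_dir: str | Path,
    gradients: Sequence[float] = DEFAULT_GRADIENTS,
    group_labels: pd.Series | dict | None = None,
) -> list[Path]:
    """Write the full six-figure bundle (PNG + TSV series each) to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for parameter in HISTOGRAM_PARAMETERS:
        fig, series = plot_histogram(rows, parameter)
        name = f"hist_{parameter}"
        _save(fig, series, out_dir, name)
        written.append(out_dir / f"{name}.png")
    fig, series = plot_sei_bei(rows, gradients=gradients, group_labels=group_labels)
    _save(fig, series, out_dir, "sei_bei")
    written.append(out_dir / "sei_bei.png")
    fig, series = plot_nsei_nbei(rows, group_labels=group_labels)
    _save(fig, series, out_dir, "nsei_nbei")
    written.append(out_dir / "nsei_nbei.png")
    return written
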