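"""Figure panels from simulation outputs (matplotlib, non-interactive)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .params import DRUGS


def _person_year_tables(run_dir: Path) -> dict:
    out = {}
    for path in sorted(run_dir.glob("person_years_*.csv")):
        df = pd.read_csv(path)
        out[df["scenario"].iloc[0]] = df
    return out


def plot_drug_use(tables: dict, ax_grid) -> None:
    """Percent of people with OA using each drug class, by scenario (panel
    per drug; the medication scenarios should jump at the start year)."""
    for ax, drug in zip(ax_grid.ravel(), DRUGS):
        for name, df in tables.items():
            if name == "Suppressed-treatment":
                continue
            g = df.groupby("year")[[f"users_{drug}", "oa_count"]].sum()
            ax.plot(g.index, 100 * g[f"users_{drug}"] / g["oa_count"], label=name)
        ax.set_title(drug)
        ax.set_ylabel("% of OA using")
    ax_grid.ravel()[0].legend(fontsize=6)


def plot_jrs_rates(tables: dict, ax) -> None:
    for name, df in tables.items():
        if name == "Suppressed-treatment":
            continue
        g = df.groupby("year")[["primary_jrs", "oa_person_time"]].sum()
        ax.plot(g.index, 1000 * g["primary_jrs"] / g["oa_person_time"], label=name)
    ax.set_ylabel("primary JRS / 1000 OA p-y")
    ax.legend(fontsize=6)


def plot_bmi_categories(tables: dict, ax) -> None:
    for name, df in tables.items():
        if name == "Suppressed-treatment":
            continue
        g = df.groupby("year")[["obese", "overweight", "population"]].sum()
        ax.plot(g.index, 100 * g["obese"] / g["population"], label=f"{name} obese")
    ax.set_ylabel("% obese")
    ax.legend(fontsize=5)


def plot_mean_hui3(tables: dict, ax) -> None:
    for name, df in tables.items():
        if name == "Suppressed-treatment":
            continue
        g = df.groupby("year")[["util_pt_oa", "oa_person_time"]].sum()
        ax.plot(g.index, g["util_pt_oa"] / g["oa_person_time"], label=name)
    ax.set_ylabel("mean HUI3 among OA")
    ax.legend(fontsize=5)


def plot_cumulative_dalys(ledger: pd.DataFrame, ax, column="cum_dalys_averted") -> None:
    for (name, sex), sub in ledger.groupby(["scenario", "sex"]):
        if name == "Base-case":
            continue
        ax.plot(sub["year"], sub[column], label=f"{name} ({sex})",
                linestyle="-" if sex == "male" else "--")
    ax.set_ylabel(column)
    ax.legend(fontsize=5)


def plot_tornado(result: pd.DataFrame, scenario: str, ax,
                 column: str = "effect_vs_base", top: int = 10) -> None:
    """Horizontal tornado bars for a one-way sensitivity result table."""
    from .sensitivity import tornado_ranges

    tr = tornado_ranges(result, scenario, column=column).head(top)[::-1]
    centre = result[(result.scenario == scenario)
                    & (result.which == "mean")][column].mean()
    ax.barh(tr["parameter"], tr["high"] - tr["low"], left=tr["low"],
            color="tab:blue", alpha=0.7)
    ax.axvline(centre, color="k", lw=0.8)
    ax.set_xlabel(column)
    ax.set_title(f"one-way sensitivity: {scenario}")


def render_tornado(result: pd.DataFrame, out_path: Path,
                   scenario: str, column: str = "effect_vs_base") -> Path:
    fig, ax = plt.subplots(figsize=(7, 5), constrained_layout=True)
    plot_tornado(result, scenario, ax, column=column)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def render_report(run_dir: Path, out_dir: Path) -> list[Path]:
    """Write the six standard panels as PNGs; returns the written paths."""
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = _person_year_tables(run_dir)
    ledger = pd.read_csv(run_dir / "ledger.csv")
    written = []

    fig, axes = plt.subplots(2, 2, figsize=(9, 6), constrained_layout=True)
    plot_drug_use(tables, axes)
    written.append(out_dir / "fig1_drug_use.png")
    fig.savefig(written[-1], dpi=120)
    plt.close(fig)

    for fname, plotter in (("fig2_jrs_rates.png", plot_jrs_rates),
                           ("fig3_bmi_categories.png", plot_bmi_categories),
                           ("fig4_mean_hui3.png", plot_mean_hui3)):
        fig, ax = plt.subplots(figsize=(7, 4), constrained_layout=True)
        plotter(tables, ax)
        written.append(out_dir / fname)
        fig.savefig(written[-1], dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4), constrained_layout=True)
    plot_cumulative_dalys(ledger, ax)
    written.append(out_dir / "fig5_cum_dalys_averted.png")
    fig.savefig(written[-1], dpi=120)
    plt.close(fig)

    if "pct_total_dalys" in ledger.columns:
        fig, ax = plt.subplots(figsize=(7, 4), constrained_layout=True)
        plot_cumulative_dalys(ledger, ax, column="pct_total_dalys")
        written.append(out_dir / "fig6_pct_total_dalys.png")
        fig.savefig(written[-1], dpi=120)
        plt.close(fig)
    return written
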