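"""Report assembly: runs a full comparison and writes tabular outputs.

The entry point :func:`run_comparison` produces the per-strategy summary
table (discounted cost, discounted diagnosed years, deltas and ICER, per
100 individuals screened), the per-cycle traces of both arms, and a run
manifest recording the configuration, seed, software version and every file
written.  All randomness in a run flows from a single seed; stage-specific
streams are derived from it deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .cea import compare
from .cohort import LifeTable, run_comparison_pair
from .parameters import ModelParameters, load_parameters
from .sensitivity import (
    ceac,
    cep_quadrant_counts,
    discount_scenarios,
    one_way,
    run_psa,
)

__all__ = ["RunManifest", "run_comparison", "run_psa_report", "run_oneway_report",
           "run_scenarios_report", "DEFAULT_WTA_GRID"]

logger = logging.getLogger(__name__)

DEFAULT_WTA_GRID = tuple(range(0, 5001, 50))


@dataclasses.dataclass
class RunManifest:
    """What a run used and what it wrote."""

    comparison: str
    seed: int | None
    version: str
    config: dict[str, Any]
    outputs: dict[str, str]
    timestamp: str

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))

    def validate_outputs(self) -> None:
        missing = [p for p in self.outputs.values() if not Path(p).exists()]
        if missing:
            raise RuntimeError(f"manifest lists missing outputs: {missing}")


def _manifest(
    comparison: str,
    params: ModelParameters,
    seed: int | None,
    outputs: Mapping[str, Path],
    outdir: Path,
) -> RunManifest:
    manifest = RunManifest(
        comparison=comparison,
        seed=seed,
        version=__version__,
        config=params.to_config(),
        outputs={k: str(v) for k, v in outputs.items()},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.validate_outputs()
    manifest.write(outdir / "manifest.json")
    return manifest


def _log_effective_parameters(params: ModelParameters) -> None:
    c = params.effective_costs()
    logger.info(
        "effective parameters: prevalence=%.4f Se=%.4f Sp=%.4f screen=$%.2f "
        "diag_test=$%.2f first_year=$%.2f diagnosed=$%.2f undiagnosed=$%.2f "
        "no_fasd=$%.2f r=%.4f",
        params.prevalence,
        params.tool.sensitivity,
        params.tool.specificity,
        params.tool.unit_cost,
        c.diagnostic_testing,
        c.first_year,
        c.diagnosed_annual,
        c.undiagnosed_annual,
        c.no_fasd_annual,
        params.discount_rate,
    )


def run_comparison(
    comparison: str,
    config: Any = None,
    outdir: str | Path = "outputs",
    life_table: LifeTable | None = None,
    discount_rate: float | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Run one screening comparison deterministically and write its tables."""
    params = load_parameters(config, comparison=comparison)
    if discount_rate is not None:
        params = dataclasses.replace(params, discount_rate=discount_rate)
    _log_effective_parameters(params)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, scr = run_comparison_pair(params, life_table)
    result = compare(ref, scr, params.cohort_size)
    ref_cost, ref_eff = ref.per_100(params.cohort_size)
    scr_cost, scr_eff = scr.per_100(params.cohort_size)
    label = "Meconium Testing" if comparison == "meconium" else "The NST"
    summary = pd.DataFrame(
        [
            {
                "strategy": "No screening",
                "discount_rate": params.discount_rate,
                "cost": round(ref_cost, 2),
                "effectiveness": round(ref_eff, 2),
                "delta_cost": None,
                "delta_effectiveness": None,
                "icer": None,
                "quadrant": None,
            },
            {
                "strategy": label,
                "discount_rate": params.discount_rate,
                "cost": round(scr_cost, 2),
                "effectiveness": round(scr_eff, 2),
                "delta_cost": round(result.delta_cost, 2),
                "delta_effectiveness": round(result.delta_effect, 2),
                "icer": None if result.icer is None else round(result.icer, 2),
                "quadrant": result.quadrant,
            },
        ]
    )
    outputs = {
        "summary": outdir / f"{comparison}_summary.csv",
        "trace_no_screen": outdir / f"{comparison}_trace_no_screen.csv",
        "trace_screen": outdir / f"{comparison}_trace_screen.csv",
    }
    summary.to_csv(outputs["summary"], index=False)
    ref.trace_frame().to_csv(outputs["trace_no_screen"], index=False)
    scr.trace_frame().to_csv(outputs["trace_screen"], index=False)
    return _manifest(comparison, params, seed, outputs, outdir)


def run_psa_report(
    comparison: str,
    config: Any = None,
    outdir: str | Path = "outputs",
    n_draws: int = 5000,
    seed: int = 20190101,
    wta_grid: tuple[float, ...] = DEFAULT_WTA_GRID,
    life_table: LifeTable | None = None,
    plot: bool = False,
) -> RunManifest:
    """Probabilistic analysis: draws, CEAC and CEP tables (optionally figures)."""
    params = load_parameters(config, comparison=comparison)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    psa = run_psa(params, n_draws=n_draws, seed=seed, life_table=life_table)
    curve = ceac(psa, wta_grid)
    quadrants = cep_quadrant_counts(psa)
    outputs = {
        "draws": outdir / f"{comparison}_psa_draws.csv",
        "ceac": outdir / f"{comparison}_ceac.csv",
        "cep_quadrants": outdir / f"{comparison}_cep_quadrants.csv",
    }
    psa.to_frame().to_csv(outputs["draws"], index=False)
    pd.DataFrame(
        [{"wta": p.wta, "probability": p.probability} for p in curve]
    ).to_csv(outputs["ceac"], index=False)
    pd.DataFrame(
        [{"quadrant": q, "count": c} for q, c in quadrants.items()]
    ).to_csv(outputs["cep_quadrants"], index=False)
    if plot:
        outputs.update(_plot_psa(comparison, psa, curve, outdir))
    return _manifest(comparison, params, seed, outputs, outdir)


def _plot_psa(comparison: str, psa, curve, outdir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot([p.wta for p in curve], [p.probability for p in curve])
    ax.set_xlabel("Willingness to accept ($ per diagnosed year forgone)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ceac_png = outdir / f"{comparison}_ceac.png"
    fig.savefig(ceac_png, dpi=150, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(psa.delta_effect, psa.delta_cost, s=4, alpha=0.3)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental diagnosed years (per 100 screened)")
    ax.set_ylabel("Incremental cost ($ per 100 screened)")
    cep_png = outdir / f"{comparison}_cep.png"
    fig.savefig(cep_png, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return {"ceac_plot": ceac_png, "cep_plot": cep_png}


def run_oneway_report(
    comparison: str,
    config: Any = None,
    outdir: str | Path = "outputs",
    life_table: LifeTable | None = None,
) -> RunManifest:
    """Tornado analysis report."""
    params = load_parameters(config, comparison=comparison)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = one_way(params, life_table=life_table)
    outputs = {"tornado": outdir / f"{comparison}_tornado.csv"}
    pd.DataFrame([dataclasses.asdict(e) for e in entries]).to_csv(
        outputs["tornado"], index=False
    )
    return _manifest(comparison, params, None, outputs, outdir)


def run_scenarios_report(
    comparison: str,
    rates: tuple[float, ...],
    config: Any = None,
    outdir: str | Path = "outputs",
    life_table: LifeTable | None = None,
) -> RunManifest:
    """Discount-rate scenario report."""
    params = load_parameters(config, comparison=comparison)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rate, res in discount_scenarios(params, rates, life_table):
        row = {"discount_rate": rate}
        row.update(res.as_dict())
        rows.append(row)
    outputs = {"scenarios": outdir / f"{comparison}_discount_scenarios.csv"}
    pd.DataFrame(rows).to_csv(outputs["scenarios"], index=False)
    return _manifest(comparison, params, None, outputs, outdir)
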