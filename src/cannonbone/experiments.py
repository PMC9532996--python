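"""Comparative experiment suites, regressions and hypothesis evaluation.

Two suites mirror the comparative design:

* ``unscaled`` — each morphotype at its true anatomy, plate displacement
  rescaled to its body size via the limb geometric mean (tests whether
  smaller bodies reduce relative bone loading);
* ``scaled`` — each morphotype brought to the reference species' metatarsal
  length and cortical thickness, with the reference 3 mm displacement
  (tests whether fusion itself lowers stresses under identical loading).

The reference species is by construction identical in both suites.
Downstream: OLS of peak responses on log10 body mass, explicit
strict-inequality decision rules for the two hypotheses, and safety
factors (fracture stress over peak functional stress).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidInputError, StabilityError
from .fea import Material, SimulationConfig, SimulationResult, simulate_impact
from .morphology import MorphotypeSpec, build_bone_model
from .scaling import ScalingSpec, scale_to_reference, scaled_displacement

__all__ = [
    "TABLE_COLUMNS",
    "RegressionResult",
    "HypothesisReport",
    "run_suite",
    "fit_body_size_model",
    "evaluate_hypotheses",
    "safety_factor",
    "plot_peak_stress_vs_mass",
]

log = logging.getLogger(__name__)

CONDITIONS = ("unscaled", "scaled")

TABLE_COLUMNS = [
    "species",
    "fusion",
    "condition",
    "peak_vm_mpa",
    "peak_grf_n",
    "body_mass_g",
    "displacement_mm",
    "fracture",
    "stable",
]


def run_suite(
    specs: list[MorphotypeSpec],
    scaling: ScalingSpec,
    condition: str,
    material: Material | None = None,
    config: SimulationConfig | None = None,
    n_elements: int = 100,
    return_results: bool = False,
):
    """Simulate every morphotype under one model condition.

    Returns an experiment table (one row per species) as a DataFrame with
    columns :data:`TABLE_COLUMNS`; with ``return_results`` also returns the
    per-species :class:`SimulationResult` objects.  A simulation that goes
    unstable flags its row (``stable=False``, NaN responses) and the suite
    continues, so comparative output is always produced.
    """
    if condition not in CONDITIONS:
        raise InvalidInputError(f"condition must be one of {CONDITIONS}")
    material = material or Material()
    config = config or SimulationConfig()

    rows = []
    results: dict[str, SimulationResult] = {}
    for spec in specs:
        if condition == "unscaled":
            sim_spec = spec
            disp = scaled_displacement(spec, scaling)
        else:
            sim_spec = scale_to_reference(spec, scaling)
            disp = scaling.reference_displacement
        run_cfg = replace(config, plate_travel=disp)
        model = build_bone_model(
            sim_spec, n_elements=n_elements, contact="distal_epiphysis"
        )
        row = {
            "species": spec.name,
            "fusion": spec.fusion,
            "condition": condition,
            "body_mass_g": spec.body_mass,
            "displacement_mm": disp,
        }
        try:
            res = simulate_impact(model, material, run_cfg)
        except StabilityError as exc:
            log.warning("%s/%s unstable: %s", spec.name, condition, exc)
            row.update(
                peak_vm_mpa=np.nan, peak_grf_n=np.nan, fracture=False, stable=False
            )
        else:
            results[spec.name] = res
            row.update(
                peak_vm_mpa=res.peak_vm / 1e6,
                peak_grf_n=res.peak_grf,
                fracture=res.fracture,
                stable=True,
            )
        rows.append(row)
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if return_results:
        return table, results
    return table


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of a peak response against the body-size covariate."""

    slope: float
    intercept: float
    p_value: float  # two-sided t-test on the slope
    adjusted_r2: float
    n: int

    def __str__(self) -> str:
        return (
            f"slope={self.slope:.4g}, intercept={self.intercept:.4g}, "
            f"p={self.p_value:.3g}, adj R^2={self.adjusted_r2:.3g}, n={self.n}"
        )


def fit_body_size_model(
    table: pd.DataFrame,
    response: str = "peak_grf_n",
    covariate: str = "log10_mass",
) -> RegressionResult:
    """Ordinary least squares of a peak response on body size.

    The default covariate is log10 body mass (a transparent stand-in for
    phylogenetically derived relative body mass, which needs data outside
    this package's scope).  ``covariate="body_mass_g"`` uses raw grams.
    """
    sub = table.dropna(subset=[response])
    if len(sub) < 3:
        raise InvalidInputError("need at least 3 rows for a regression")
    if covariate == "log10_mass":
        x = np.log10(sub["body_mass_g"].to_numpy(float))
    else:
        x = sub[covariate].to_numpy(float)
    if np.ptp(x) == 0.0:
        raise InvalidInputError("degenerate covariate: zero variance")
    y = sub[response].to_numpy(float)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_value=float(fit.pvalues[1]),
        adjusted_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
    )


@dataclass(frozen=True)
class HypothesisReport:
    """Outcome of the two comparative hypotheses on a pair of suite tables.

    H1: reduced body mass relative to foot length lowers relative bone
    loading — supported iff, in the unscaled suite, every smaller-bodied
    unfused species' peak stress lies strictly below the fused reference's.

    H2: fusion lowers stresses under identical loading — supported iff, in
    the scaled suite, every fused or partially fused morphotype's peak
    stress is strictly below every unfused morphotype's.
    """

    h1_supported: bool
    h2_supported: bool
    unscaled_ranking: tuple[tuple[str, float], ...]
    scaled_ranking: tuple[tuple[str, float], ...]

    def __str__(self) -> str:
        def fmt(ranking):
            return "\n".join(
                f"    {name:<14s} {vm:8.1f} MPa" for name, vm in ranking
            )

        return (
            "hypothesis evaluation\n"
            f"  H1 (small body size lowers relative loading): "
            f"{'supported' if self.h1_supported else 'NOT supported'}\n"
            f"  H2 (fusion lowers stress at equal loading):   "
            f"{'supported' if self.h2_supported else 'NOT supported'}\n"
            "  unscaled peak stresses (descending):\n" + fmt(self.unscaled_ranking)
            + "\n  scaled peak stresses (descending):\n" + fmt(self.scaled_ranking)
        )


def _ranking(table: pd.DataFrame) -> tuple[tuple[str, float], ...]:
    sub = table.dropna(subset=["peak_vm_mpa"]).sort_values(
        "peak_vm_mpa", ascending=False
    )
    return tuple((r.species, float(r.peak_vm_mpa)) for r in sub.itertuples())


def evaluate_hypotheses(
    unscaled: pd.DataFrame, scaled: pd.DataFrame
) -> HypothesisReport:
    """Apply the explicit strict-inequality decision rules to both suites."""
    for tbl in (unscaled, scaled):
        if tbl["fusion"].isna().any() or not set(tbl["fusion"]) <= {
            "unfused",
            "partial",
            "fused",
        }:
            raise InvalidInputError("missing or unknown fusion labels")

    sc = scaled.dropna(subset=["peak_vm_mpa"])
    fused_like = sc.loc[sc.fusion.isin(["fused", "partial"]), "peak_vm_mpa"]
    unfused = sc.loc[sc.fusion == "unfused", "peak_vm_mpa"]
    h2 = (
        len(fused_like) > 0
        and len(unfused) > 0
        and float(fused_like.max()) < float(unfused.min())
    )

    un = unscaled.dropna(subset=["peak_vm_mpa"])
    ref_rows = un.loc[un.fusion == "fused"]
    if len(ref_rows):
        # the reference is the smallest-bodied fused species
        ref = ref_rows.loc[ref_rows.body_mass_g.idxmin()]
        smaller_unfused = un.loc[
            (un.fusion == "unfused") & (un.body_mass_g < float(ref.body_mass_g)),
            "peak_vm_mpa",
        ]
        h1 = len(smaller_unfused) > 0 and float(smaller_unfused.max()) < float(
            ref.peak_vm_mpa
        )
    else:
        h1 = False

    return HypothesisReport(
        h1_supported=bool(h1),
        h2_supported=bool(h2),
        unscaled_ranking=_ranking(unscaled),
        scaled_ranking=_ranking(scaled),
    )


def safety_factor(peak_vm: float, ultimate: float = 205.0) -> float:
    """Failure stress over peak functional stress (same units both inputs).

    A value above 1 means the bone survives the simulated loading; jumping
    rodents are expected to carry high safety factors in the foot.
    """
    if peak_vm <= 0.0:
        raise InvalidInputError("safety factor undefined for zero peak stress")
    return ultimate / peak_vm


def plot_peak_stress_vs_mass(tables: list[pd.DataFrame], path=None):
    """Peak von Mises stress vs body mass, one panel per condition.

    The shaded band marks stresses above the fracture threshold.  Returns
    the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"unfused": "tab:blue", "partial": "tab:orange", "fused": "tab:red"}
    fig, axes = plt.subplots(1, len(tables), figsize=(5 * len(tables), 4), squeeze=False)
    for ax, table in zip(axes[0], tables):
        for fusion, grp in table.groupby("fusion"):
            ax.scatter(
                grp.body_mass_g, grp.peak_vm_mpa, label=fusion,
                color=colors.get(fusion, "k"),
            )
        ax.axhspan(205.0, max(260.0, table.peak_vm_mpa.max() * 1.1), alpha=0.15,
                   color="grey")
        ax.set_xscale("log")
        ax.set_xlabel("body mass (g)")
        ax.set_ylabel("peak von Mises stress (MPa)")
        ax.set_title(str(table.condition.iloc[0]))
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
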