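"""Radiation-vs-accuracy trade-off Monte Carlo.

Hybrid navigation replaces some snapshot triplets by EMT positions. The
leave-out experiment quantifies what that costs in accuracy and saves in
radiation: for each M in 0..60, M of the 60 navigation steps are replaced
(uniformly, without replacement) by their EMT position, whose error against
the X-ray reference is the dataset's actual compensation residual; the
remaining X-ray-navigated steps carry a modeled per-axis Gaussian position
error (sigma = 0.32 mm, the pixel quantization noise). Repeating this for
N iterations yields, per M, the mean per-step error, a conservative CI-95
accuracy bound (the 95th percentile of the per-iteration RMSE values), and
the fluoroscopy time (FT) / dose area product (DAP) of the retained
exposures. The operating point is where the CI-95 bound first satisfies
the 1 mm high-precision requirement.

A second Monte Carlo measures how the achievable radiation saving degrades
as the number of compensation training points shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .compensation import CompensationModel, TrainingSet, basis_size
from .errors import ConfigurationError, UnderdeterminedFitError

__all__ = [
    "RadiationModel",
    "MCConfig",
    "TradeoffCurve",
    "SavingCurve",
    "radiation_totals",
    "percent_reduction",
    "leaveout_mc",
    "ft_at_threshold",
    "training_reduction_mc",
    "plot_tradeoff",
    "plot_saving",
]


@dataclass(frozen=True)
class RadiationModel:
    """Per-exposure radiation bookkeeping.

    The C-arm reports 0.95 s fluoroscopy time and 0.28 cGy*cm^2 DAP per
    snapshot; totals are these averages times the number of exposures.
    ``exposures_per_event`` selects the accounting mode: 1 exposure per
    retained navigation event (consistent with the 60 s full-acquisition
    baseline), or 3 for full-triplet accounting.
    """

    ft_per_xray_s: float = 0.95
    dap_per_xray: float = 0.28
    exposures_per_event: int = 1
    baseline_ft_s: float = 60.0

    def __post_init__(self) -> None:
        if not (
            self.ft_per_xray_s > 0 and self.dap_per_xray > 0 and self.baseline_ft_s > 0
        ):
            raise ConfigurationError("radiation parameters must be > 0")
        if self.exposures_per_event not in (1, 3):
            raise ConfigurationError("exposures_per_event must be 1 or 3")


@dataclass
class MCConfig:
    """Leave-out Monte Carlo configuration (defaults are the study
    conditions: M = 0..60, N = 200, sigma = 0.32 mm, CI-95, 1 mm)."""

    m_values: Sequence[int] = field(default_factory=lambda: range(0, 61))
    n_iterations: int = 200
    sigma_mm: float = 0.32
    seed: int = 0
    threshold_mm: float = 1.0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        self.m_values = list(self.m_values)
        if self.sigma_mm < 0:
            raise ConfigurationError("sigma_mm must be >= 0")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigurationError("ci_level must lie in (0, 1)")
        if any(m < 0 for m in self.m_values):
            raise ConfigurationError("m_values must be >= 0")


@dataclass
class TradeoffCurve:
    """Per-M error statistics and radiation totals, as a tidy DataFrame
    with columns (compensation, M, n_exposures, FT_s, DAP, err_mean_mm,
    err_ci95_mm)."""

    data: pd.DataFrame
    label: str = "none"

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TradeoffCurve":
        df = pd.read_csv(path)
        label = str(df["compensation"].iloc[0]) if len(df) else "none"
        return cls(data=df, label=label)


@dataclass
class SavingCurve:
    """Mean radiation saving (percent of the baseline FT) per number of
    training points, with its Monte Carlo spread."""

    data: pd.DataFrame  # columns: n_train, saving_mean_pct, saving_std_pct
    iterations: int

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def radiation_totals(n_exposures: int, model: RadiationModel) -> Tuple[float, float]:
    """(FT_s, DAP) for a number of exposures: averages times the count."""
    if n_exposures < 0:
        raise ConfigurationError("n_exposures must be >= 0")
    return (
        n_exposures * model.ft_per_xray_s,
        n_exposures * model.dap_per_xray,
    )


def percent_reduction(baseline_ft_s: float, hybrid_ft_s: float) -> float:
    """Radiation saving in percent: 100 (baseline - hybrid) / baseline."""
    if baseline_ft_s <= 0:
        raise ConfigurationError("baseline_ft_s must be > 0")
    if not 0.0 <= hybrid_ft_s <= baseline_ft_s:
        raise ConfigurationError(
            "hybrid FT must lie in [0, baseline]; no negative savings reported"
        )
    return 100.0 * (baseline_ft_s - hybrid_ft_s) / baseline_ft_s


def leaveout_mc(
    emt_points,
    reference_points,
    config: MCConfig = MCConfig(),
    radiation: RadiationModel = RadiationModel(),
    label: str = "none",
) -> TradeoffCurve:
    """Leave-out Monte Carlo over the per-step navigation dataset.

    Parameters
    ----------
    emt_points, reference_points:
        (n_steps, 3) arrays in the image frame: the (compensated or merely
        rigidly registered) EMT position for each step, and the X-ray
        reference for the same step. Their per-step distance is the error
        paid whenever a step's snapshot is replaced by EMT.
    config, radiation:
        Monte Carlo and radiation bookkeeping parameters.
    label:
        Compensation label recorded in the output ('none'/'linear'/'cubic').

    For each M and iteration, M distinct steps are drawn to be replaced;
    replaced steps contribute their actual EMT-vs-reference distance, kept
    steps a fresh ||N(0, sigma^2 I_3)|| draw. Per M the curve records the
    pooled mean per-step error and the CI-95 accuracy bound — the
    ``ci_level`` quantile over iterations of the per-iteration combined
    RMSE (root of the mean per-axis MSE over the steps, the same scale as
    :class:`~hybridnav.registration.ErrorReport`; for a pure Gaussian
    iteration it equals sigma in expectation). The whole curve is a
    deterministic function of (dataset, config, seed).
    """
    emt = np.asarray(emt_points, dtype=float).reshape(-1, 3)
    ref = np.asarray(reference_points, dtype=float).reshape(-1, 3)
    if emt.shape != ref.shape:
        raise ConfigurationError("EMT and reference arrays must have equal shapes")
    n_steps = len(emt)
    if any(m > n_steps for m in config.m_values):
        raise ConfigurationError("M cannot exceed the number of steps")
    step_err = np.linalg.norm(emt - ref, axis=1)
    rng = np.random.default_rng(config.seed)
    rows = []
    for m in config.m_values:
        # Uniform M-subsets without replacement, one per iteration.
        order = np.argsort(
            rng.random((config.n_iterations, n_steps)), axis=1, kind="stable"
        )
        replaced = np.zeros((config.n_iterations, n_steps), dtype=bool)
        np.put_along_axis(replaced, order[:, :m], True, axis=1)
        gauss = rng.normal(
            0.0, config.sigma_mm, size=(config.n_iterations, n_steps, 3)
        )
        kept_err = np.linalg.norm(gauss, axis=2)
        err = np.where(replaced, step_err[None, :], kept_err)
        # Combined RMSE per iteration: mean squared *norm* over steps is the
        # sum of the three per-axis MSEs, so divide by 3.
        rmse_iter = np.sqrt(np.mean(err**2, axis=1) / 3.0)
        n_exposures = (n_steps - m) * radiation.exposures_per_event
        ft_s, dap = radiation_totals(n_exposures, radiation)
        rows.append(
            {
                "compensation": label,
                "M": m,
                "n_exposures": n_exposures,
                "FT_s": ft_s,
                "DAP": dap,
                "err_mean_mm": float(err.mean()),
                "err_ci95_mm": float(np.quantile(rmse_iter, config.ci_level)),
            }
        )
    return TradeoffCurve(data=pd.DataFrame(rows), label=label)


def ft_at_threshold(
    curve: TradeoffCurve, threshold_mm: float = 1.0
) -> Optional[float]:
    """Smallest fluoroscopy time among curve points whose CI-95 accuracy
    bound meets the threshold; ``None`` when no point qualifies (the
    accuracy requirement is not achievable at any exposure count)."""
    df = curve.data
    if len(df) == 0:
        raise ConfigurationError("empty trade-off curve")
    ok = df[df["err_ci95_mm"] <= threshold_mm]
    if len(ok) == 0:
        return None
    return float(ok["FT_s"].min())


def training_reduction_mc(
    training_set: TrainingSet,
    k_values: Sequence[int],
    degree: int,
    emt_raw_points,
    reference_points,
    config: MCConfig = MCConfig(),
    radiation: RadiationModel = RadiationModel(),
    iterations: int = 1000,
    seed: int = 0,
) -> SavingCurve:
    """Radiation saving as a function of the number of training points.

    Per ``k`` and iteration: subsample ``k`` of the training pairs
    uniformly without replacement, refit the degree-``degree``
    compensation, map the raw EMT evaluation points through it, rerun the
    leave-out Monte Carlo and record the percent FT reduction at the
    threshold (zero when the threshold is never met). The returned curve
    aggregates the mean and standard deviation of the saving per ``k``.
    """
    nb = basis_size(degree)
    train_idx = np.flatnonzero(training_set.train_mask)
    for k in k_values:
        if k < nb:
            raise UnderdeterminedFitError(
                f"k={k} training points cannot determine a degree-{degree} "
                f"fit ({nb} basis terms)"
            )
        if k > len(train_idx):
            raise ConfigurationError(f"k={k} exceeds {len(train_idx)} training points")
    emt_raw = np.asarray(emt_raw_points, dtype=float).reshape(-1, 3)
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_values:
        savings = np.empty(iterations)
        for it in range(iterations):
            subset = rng.choice(train_idx, size=k, replace=False)
            sub = TrainingSet(
                src=training_set.src[subset],
                dst=training_set.dst[subset],
                split=np.array(["train"] * k, dtype=object),
            )
            model = CompensationModel.fit(sub, degree=degree)
            mapped = model.apply(emt_raw)
            run_cfg = MCConfig(
                m_values=config.m_values,
                n_iterations=config.n_iterations,
                sigma_mm=config.sigma_mm,
                seed=int(rng.integers(0, 2**31 - 1)),
                threshold_mm=config.threshold_mm,
                ci_level=config.ci_level,
            )
            curve = leaveout_mc(mapped, reference_points, run_cfg, radiation)
            ft = ft_at_threshold(curve, config.threshold_mm)
            savings[it] = (
                0.0
                if ft is None
                else percent_reduction(radiation.baseline_ft_s, min(ft, radiation.baseline_ft_s))
            )
        rows.append(
            {
                "n_train": int(k),
                "saving_mean_pct": float(savings.mean()),
                "saving_std_pct": float(savings.std(ddof=0)),
            }
        )
    return SavingCurve(data=pd.DataFrame(rows), iterations=iterations)


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------


def plot_tradeoff(
    curves: Iterable[TradeoffCurve],
    threshold_mm: float = 1.0,
    path=None,
):
    """Error vs fluoroscopy time for one or more curves, with the
    high-precision threshold band; optionally saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for curve in curves:
        df = curve.data.sort_values("FT_s")
        ax.plot(df["FT_s"], df["err_mean_mm"], label=f"{curve.label} (mean)")
        ax.plot(
            df["FT_s"],
            df["err_ci95_mm"],
            linestyle="--",
            marker=".",
            label=f"{curve.label} (CI-95)",
        )
    ax.axhspan(0.0, threshold_mm, color="green", alpha=0.12, label="high-precision band")
    ax.set_xlabel("fluoroscopy time (s)")
    ax.set_ylabel("tracking error (mm)")
    ax.set_yscale("log")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_saving(curve: SavingCurve, path=None):
    """Radiation saving over the number of training points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    df = curve.data
    ax.errorbar(
        df["n_train"], df["saving_mean_pct"], yerr=df["saving_std_pct"], marker="o"
    )
    ax.set_xlabel("number of training points")
    ax.set_ylabel("FT saving (%)")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
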