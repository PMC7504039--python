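"""1:1 Langmuir binding kinetics for SPR sensorgrams.

The surface-binding model is the pseudo-first-order Langmuir scheme

    dR/dt = k_on · C · (Rmax − R) − k_off · R

where R is the biosensor response (RU), C the analyte concentration (M),
Rmax the maximal response, k_on (M⁻¹s⁻¹) and k_off (s⁻¹) the rate constants,
and Kd = k_off/k_on, Ka = k_on/k_off.  During association (t ≤ t_a, constant
C) the ODE has the closed form

    R(t) = R_eq + (R0 − R_eq)·exp(−(k_on·C + k_off)·t),
    R_eq = k_on·C·Rmax / (k_on·C + k_off),

and during dissociation (t > t_a, C = 0)

    R(t) = R(t_a)·exp(−k_off·(t − t_a)).

:class:`LangmuirKineticsModel` holds a set of sensorgrams at different
analyte concentrations and globally fits shared (k_on, k_off, Rmax) by least
squares (lmfit, log-parameter space with bounds); its :meth:`fit` returns a
:class:`LangmuirKineticsResults` with estimates, standard errors, per-curve
residual sums of squares, ``summary()`` and ``plot()``.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "Sensorgram",
    "LangmuirKineticsModel",
    "LangmuirKineticsResults",
    "KineticFit",
    "langmuir_response",
    "simulate_sensorgram",
    "fit_langmuir",
    "kd_from_rates",
    "PAPER_CONCENTRATIONS_M",
]

#: default analyte dilution series, M (0–2000 µM)
PAPER_CONCENTRATIONS_M = (0.0, 50e-6, 100e-6, 200e-6, 500e-6, 1000e-6, 1500e-6, 2000e-6)

DEFAULT_T_ASSOC = 300.0  # s, association-phase duration
DEFAULT_T_TOTAL = 420.0  # s, association + 120 s dissociation

# log10 fit bounds: k_on ∈ [1e-4, 1e8] M⁻¹s⁻¹, k_off ∈ [1e-7, 1] s⁻¹, Rmax ∈ (0, 1e5] RU
_BOUNDS_LOG10 = {"kon": (-4.0, 8.0), "koff": (-7.0, 0.0), "rmax": (-3.0, 5.0)}


def langmuir_response(
    k_on: float,
    k_off: float,
    rmax: float,
    conc: float,
    t: Union[float, np.ndarray],
    t_assoc: float = DEFAULT_T_ASSOC,
    r0: float = 0.0,
) -> Union[float, np.ndarray]:
    """Closed-form 1:1 Langmuir response at time(s) ``t`` (RU).

    Association for t ≤ ``t_assoc`` from initial response ``r0``, exponential
    dissociation afterwards.  All rates, ``rmax``, ``conc`` and ``t`` must be
    non-negative.
    """
    for name, val in (("k_on", k_on), ("k_off", k_off), ("rmax", rmax), ("conc", conc)):
        if val < 0:
            raise ValueError(f"{name} must be non-negative, got {val}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    kobs = k_on * conc + k_off
    if kobs > 0:
        r_eq = k_on * conc * rmax / kobs
        assoc = r_eq + (r0 - r_eq) * np.exp(-kobs * np.minimum(t_arr, t_assoc))
    else:  # C = 0 and k_off = 0: nothing binds or unbinds
        assoc = np.full_like(t_arr, r0, dtype=float)
    # response at end of association, for the dissociation branch
    if kobs > 0:
        r_end = k_on * conc * rmax / kobs + (r0 - k_on * conc * rmax / kobs) * np.exp(
            -kobs * t_assoc
        )
    else:
        r_end = r0
    dissoc = r_end * np.exp(-k_off * np.maximum(t_arr - t_assoc, 0.0))
    out = np.where(t_arr <= t_assoc, assoc, dissoc)
    return float(out) if np.isscalar(t) else out


@dataclass
class Sensorgram:
    """One time–response curve at a single analyte concentration."""

    conc: float  # mol/L
    times: np.ndarray  # s, strictly increasing
    response: np.ndarray  # RU
    t_assoc: float = DEFAULT_T_ASSOC
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.shape != self.response.shape:
            raise ValueError("times and response must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (self.times[0] <= self.t_assoc <= self.times[-1]):
            raise ValueError("association end time must lie within the time span")
        if self.conc < 0:
            raise ValueError("concentration must be non-negative")
        if not self.label:
            self.label = f"{self.conc * 1e6:g}uM"


def simulate_sensorgram(
    k_on: float,
    k_off: float,
    rmax: float,
    concentrations: Sequence[float] = PAPER_CONCENTRATIONS_M,
    t_assoc: float = DEFAULT_T_ASSOC,
    t_total: float = DEFAULT_T_TOTAL,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    baseline: float = 0.0,
) -> List[Sensorgram]:
    """Simulate one sensorgram per concentration with additive Gaussian noise.

    Deterministic given ``seed``; the zero-concentration curve is pure noise
    around the baseline.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_total + dt / 2, dt)
    out = []
    for conc in concentrations:
        clean = langmuir_response(k_on, k_off, rmax, conc, times, t_assoc) + baseline
        noisy = clean + rng.normal(0.0, noise_sd, size=times.shape) if noise_sd else clean
        out.append(Sensorgram(conc=conc, times=times, response=noisy, t_assoc=t_assoc))
    return out


def kd_from_rates(k_on: float, k_off: float) -> Tuple[float, float]:
    """(Kd, Ka) from the rate constants: Kd = k_off/k_on, Ka = k_on/k_off."""
    if k_on <= 0:
        raise ValueError(f"k_on must be positive, got {k_on}")
    if k_off < 0:
        raise ValueError(f"k_off must be non-negative, got {k_off}")
    kd = k_off / k_on
    if k_off == 0:
        raise ValueError("Ka = k_on/k_off is undefined for k_off = 0 (Kd would be 0)")
    return kd, k_on / k_off


def sensorgrams_to_dataframe(sensorgrams: Sequence[Sensorgram]) -> pd.DataFrame:
    """Long-format table with columns time_s, response_RU, conc_M, curve_id."""
    frames = []
    for sg in sensorgrams:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": sg.times,
                    "response_RU": sg.response,
                    "conc_M": sg.conc,
                    "curve_id": sg.label,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class LangmuirKineticsModel:
    """Global 1:1 Langmuir kinetic model over multi-concentration sensorgrams.

    Parameters
    ----------
    sensorgrams
        Curves at distinct analyte concentrations (≥2 with C > 0 recommended;
        fewer triggers a warning, not an error).
    mask_windows
        Optional list of (t_start, t_end) time intervals excluded from the
        fit (e.g. injection spikes at phase boundaries).
    """

    def __init__(
        self,
        sensorgrams: Sequence[Sensorgram],
        mask_windows: Optional[Sequence[Tuple[float, float]]] = None,
    ):
        if not sensorgrams:
            raise ValueError("at least one sensorgram is required")
        self.sensorgrams = list(sensorgrams)
        self.mask_windows = [tuple(w) for w in (mask_windows or [])]
        n_pos = len({sg.conc for sg in self.sensorgrams if sg.conc > 0})
        if n_pos < 2:
            warnings.warn(
                f"only {n_pos} distinct positive analyte concentration(s); the global "
                "fit may be poorly constrained",
                stacklevel=2,
            )
        if all(np.allclose(sg.response, 0) for sg in self.sensorgrams):
            raise ValueError("all responses are zero; nothing to fit")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        t_assoc: float = DEFAULT_T_ASSOC,
        time_col: str = "time_s",
        response_col: str = "response_RU",
        conc_col: str = "conc_M",
        curve_col: str = "curve_id",
        mask_windows: Optional[Sequence[Tuple[float, float]]] = None,
    ) -> "LangmuirKineticsModel":
        """Build from a long-format table (one row per sample)."""
        sensorgrams = []
        for curve_id, sub in df.groupby(curve_col, sort=False):
            sub = sub.sort_values(time_col)
            sensorgrams.append(
                Sensorgram(
                    conc=float(sub[conc_col].iloc[0]),
                    times=sub[time_col].to_numpy(),
                    response=sub[response_col].to_numpy(),
                    t_assoc=t_assoc,
                    label=str(curve_id),
                )
            )
        return cls(sensorgrams, mask_windows=mask_windows)

    @classmethod
    def from_csv(cls, path: Union[str, Path], **kwargs) -> "LangmuirKineticsModel":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls.from_dataframe(pd.read_csv(path, sep=sep), **kwargs)

    # -- fitting ---------------------------------------------------------

    def _fit_mask(self, sg: Sensorgram) -> np.ndarray:
        keep = np.ones_like(sg.times, dtype=bool)
        for t0, t1 in self.mask_windows:
            keep &= ~((sg.times >= t0) & (sg.times <= t1))
        return keep

    def _initial_guess(self) -> Dict[str, float]:
        """Linearized starting values: k_obs = k_on·C + k_off regressed on C."""
        kobs_pts = []
        plateaus = []
        koff_dissoc = []
        for sg in self.sensorgrams:
            if sg.conc <= 0:
                continue
            assoc = sg.times <= sg.t_assoc
            t_a, r_a = sg.times[assoc], sg.response[assoc]
            if len(t_a) < 4:
                continue
            plateau = float(np.mean(r_a[-max(3, len(r_a) // 10) :]))
            plateaus.append((sg.conc, plateau))
            # log-linear estimate of k_obs from 1 - R/plateau over the rising part
            if plateau > 0:
                frac = 1.0 - r_a / (plateau * 1.05)
                ok = (frac > 0.05) & (t_a > 0)
                if ok.sum() >= 3:
                    slope = np.polyfit(t_a[ok], np.log(frac[ok]), 1)[0]
                    if slope < 0:
                        kobs_pts.append((sg.conc, -slope))
            # dissociation decay → k_off
            dis = sg.times > sg.t_assoc
            t_d, r_d = sg.times[dis], sg.response[dis]
            ok = r_d > max(1e-6, 0.02 * abs(plateau))
            if ok.sum() >= 3:
                slope = np.polyfit(t_d[ok], np.log(r_d[ok]), 1)[0]
                if slope < 0:
                    koff_dissoc.append(-slope)

        kon0, koff0 = 1.0, 1e-3
        if len(kobs_pts) >= 2:
            cs = np.array([c for c, _ in kobs_pts])
            ks = np.array([k for _, k in kobs_pts])
            slope, intercept = np.polyfit(cs, ks, 1)
            if slope > 0:
                kon0 = slope
            if intercept > 0:
                koff0 = intercept
        if koff_dissoc:
            koff0 = float(np.median(koff_dissoc))
        rmax0 = max((p for _, p in plateaus), default=1.0)
        if plateaus and kon0 > 0:
            ests = [p * (kon0 * c + koff0) / (kon0 * c) for c, p in plateaus if c > 0]
            rmax0 = float(np.median(ests))

        def clip(v, key):
            lo, hi = _BOUNDS_LOG10[key]
            return float(np.clip(np.log10(max(v, 1e-300)), lo + 0.01, hi - 0.01))

        return {
            "log_kon": clip(kon0, "kon"),
            "log_koff": clip(koff0, "koff"),
            "log_rmax": clip(rmax0, "rmax"),
        }

    def _residuals(self, params: lmfit.Parameters) -> np.ndarray:
        kon = 10.0 ** params["log_kon"].value
        koff = 10.0 ** params["log_koff"].value
        rmax = 10.0 ** params["log_rmax"].value
        baseline = params["baseline"].value if "baseline" in params else 0.0
        res = []
        for sg in self.sensorgrams:
            keep = self._fit_mask(sg)
            model = (
                langmuir_response(kon, koff, rmax, sg.conc, sg.times[keep], sg.t_assoc)
                + baseline
            )
            res.append(sg.response[keep] - model)
        return np.concatenate(res)

    def fit(
        self,
        fit_baseline: Optional[bool] = None,
        init: Optional[Dict[str, float]] = None,
        method: str = "leastsq",
    ) -> "LangmuirKineticsResults":
        """Globally fit (k_on, k_off, Rmax) shared across all curves.

        ``fit_baseline`` adds a constant offset parameter; by default it is
        enabled when a zero-concentration curve is present (that curve then
        anchors the offset).  ``init`` may override the linearized starting
        values with plain-unit entries ('kon', 'koff', 'rmax').
        """
        if fit_baseline is None:
            fit_baseline = any(sg.conc == 0 for sg in self.sensorgrams)
        guess = self._initial_guess()
        if init:
            for key in ("kon", "koff", "rmax"):
                if key in init:
                    lo, hi = _BOUNDS_LOG10[key]
                    guess[f"log_{key}"] = float(
                        np.clip(np.log10(init[key]), lo + 0.01, hi - 0.01)
                    )
        params = lmfit.Parameters()
        for key in ("kon", "koff", "rmax"):
            lo, hi = _BOUNDS_LOG10[key]
            params.add(f"log_{key}", value=guess[f"log_{key}"], min=lo, max=hi)
        if fit_baseline:
            params.add("baseline", value=0.0)

        minres = lmfit.minimize(self._residuals, params, method=method)
        return LangmuirKineticsResults(model=self, minimizer_result=minres)


class LangmuirKineticsResults:
    """Fit results: estimates, uncertainties, diagnostics, summary table."""

    def __init__(self, model: LangmuirKineticsModel, minimizer_result):
        self.model = model
        self.minimizer_result = minimizer_result
        self.converged = bool(minimizer_result.success)
        if not self.converged:
            warnings.warn(
                "global Langmuir fit did not converge; reporting best-found "
                "parameters",
                stacklevel=2,
            )
        p = minimizer_result.params
        self.k_on = 10.0 ** p["log_kon"].value
        self.k_off = 10.0 ** p["log_koff"].value
        self.rmax = 10.0 ** p["log_rmax"].value
        self.baseline = p["baseline"].value if "baseline" in p else 0.0
        ln10 = np.log(10.0)
        self.k_on_stderr = (
            self.k_on * ln10 * p["log_kon"].stderr if p["log_kon"].stderr else None
        )
        self.k_off_stderr = (
            self.k_off * ln10 * p["log_koff"].stderr if p["log_koff"].stderr else None
        )
        self.rmax_stderr = (
            self.rmax * ln10 * p["log_rmax"].stderr if p["log_rmax"].stderr else None
        )

    # -- derived constants ------------------------------------------------

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant Kd = k_off/k_on (M)."""
        return self.k_off / self.k_on

    @property
    def ka(self) -> float:
        """Equilibrium association constant Ka = k_on/k_off (M⁻¹)."""
        return self.k_on / self.k_off

    @property
    def kd_stderr(self) -> Optional[float]:
        if self.k_on_stderr is None or self.k_off_stderr is None:
            return None
        rel = np.hypot(self.k_on_stderr / self.k_on, self.k_off_stderr / self.k_off)
        return self.kd * float(rel)

    @property
    def params(self) -> Dict[str, float]:
        return {
            "k_on": self.k_on,
            "k_off": self.k_off,
            "rmax": self.rmax,
            "baseline": self.baseline,
            "kd": self.kd,
            "ka": self.ka,
        }

    # -- diagnostics -------------------------------------------------------

    def predict(self, sensorgram: Sensorgram) -> np.ndarray:
        return (
            langmuir_response(
                self.k_on, self.k_off, self.rmax, sensorgram.conc,
                sensorgram.times, sensorgram.t_assoc,
            )
            + self.baseline
        )

    @property
    def rss_per_curve(self) -> Dict[str, float]:
        out = {}
        for sg in self.model.sensorgrams:
            keep = self.model._fit_mask(sg)
            resid = sg.response[keep] - self.predict(sg)[keep]
            out[sg.label] = float(np.sum(resid**2))
        return out

    @property
    def rss(self) -> float:
        return float(sum(self.rss_per_curve.values()))

    def fitted_curves(self) -> List[Sensorgram]:
        return [
            Sensorgram(sg.conc, sg.times, self.predict(sg), sg.t_assoc, sg.label + ":fit")
            for sg in self.model.sensorgrams
        ]

    def summary(self) -> str:
        lines = [
            "Global 1:1 Langmuir kinetic fit",
            "=" * 46,
            f"curves: {len(self.model.sensorgrams)}   converged: {self.converged}",
            f"total RSS: {self.rss:.6g}",
            "-" * 46,
            f"{'parameter':<12}{'estimate':>14}{'std err':>14}",
        ]
        for name, val, se in (
            ("k_on", self.k_on, self.k_on_stderr),
            ("k_off", self.k_off, self.k_off_stderr),
            ("Rmax", self.rmax, self.rmax_stderr),
            ("baseline", self.baseline, None),
            ("Kd", self.kd, self.kd_stderr),
            ("Ka", self.ka, None),
        ):
            se_txt = f"{se:>14.4g}" if se is not None else f"{'--':>14}"
            lines.append(f"{name:<12}{val:>14.4g}{se_txt}")
        lines.append("-" * 46)
        lines.append("units: k_on M⁻¹s⁻¹, k_off s⁻¹, Rmax/baseline RU, Kd M, Ka M⁻¹")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "stderr": {
                "k_on": self.k_on_stderr,
                "k_off": self.k_off_stderr,
                "rmax": self.rmax_stderr,
                "kd": self.kd_stderr,
            },
            "converged": self.converged,
            "rss": self.rss,
            "rss_per_curve": self.rss_per_curve,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def plot(self, ax=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for sg in self.model.sensorgrams:
            ax.plot(sg.times, sg.response, ".", ms=2, alpha=0.5)
            ax.plot(sg.times, self.predict(sg), "-", lw=1.2, label=sg.label)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("response (RU)")
        ax.legend(fontsize=7, ncol=2)
        return ax


#: the fitted-parameters object of the pipeline ("KineticFit")
KineticFit = LangmuirKineticsResults


def fit_langmuir(
    sensorgrams: Sequence[Sensorgram],
    mask_windows: Optional[Sequence[Tuple[float, float]]] = None,
    **fit_kwargs,
) -> LangmuirKineticsResults:
    """Convenience wrapper: build the model and fit in one call."""
    return LangmuirKineticsModel(sensorgrams, mask_windows=mask_windows).fit(**fit_kwargs)
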