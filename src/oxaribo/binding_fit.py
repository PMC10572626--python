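"""Ligand-depletion (quadratic) binding isotherm and Kd fitting.

For the two-component equilibrium A + B <-> AB with total concentrations
[A], [B] and dissociation constant Kd, the bound fraction of B is the exact
mass-action root

    FB = ([A] + [B] + Kd - sqrt(([A] + [B] + Kd)^2 - 4 [A][B])) / (2 [B]).

This form is required, rather than the hyperbolic approximation
FB = A/(A + Kd), whenever the labelled partner's concentration is comparable
to or above Kd (ligand depletion) -- exactly the regime of a 20 uM labelled
protein titrated with a sub-micromolar-Kd partner.  MST dose-response data
(response = 1 - Fi/Fnorm against titrant concentration) are fitted as
response = offset + amplitude * FB(A; B, Kd) by bounded nonlinear least
squares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from oxaribo.errors import FitError, FormatError, ValidationError

__all__ = [
    "DoseResponse",
    "BindingFitResult",
    "KdRegressor",
    "fraction_bound",
    "fit_kd",
    "bootstrap_ci",
    "read_dose_response",
    "write_dose_response",
]


def fraction_bound(a, b, kd):
    """Bound fraction FB = [AB]/[B] of partner B at totals ``a``, ``b`` and ``kd``.

    All three arguments must share one concentration unit; ``a`` may be an
    array.  Evaluated as 2ab / (S + sqrt(S^2 - 4ab)) with S = a + b + kd,
    which is algebraically identical to the quadratic root but avoids the
    catastrophic cancellation of the textbook form when 4ab << S^2
    (a << b or a >> b).
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValidationError("titrant concentration a must be >= 0")
    if not np.isscalar(b) and np.ndim(b) != 0:
        raise ValidationError("b must be a scalar concentration")
    b = float(b)
    kd = float(kd)
    if b <= 0:
        raise ValidationError("ligand concentration b must be > 0")
    if kd < 0:
        raise ValidationError("kd must be >= 0")
    s = a + b + kd
    disc = s * s - 4.0 * a * b
    disc = np.maximum(disc, 0.0)  # guard round-off at kd == 0, a == b
    with np.errstate(divide="ignore", invalid="ignore"):
        bound = np.where(a > 0, 2.0 * a * b / (s + np.sqrt(disc)), 0.0)
    fb = bound / b
    return float(fb) if fb.ndim == 0 else fb


@dataclass
class DoseResponse:
    """An MST dose-response curve: 1 - Fi/Fnorm against titrant concentration.

    ``titrant_conc`` is the concentration series of partner A in nM, strictly
    increasing; ``ligand_total`` the labelled partner B in uM.
    """

    titrant_conc: np.ndarray  # nM
    response: np.ndarray  # dimensionless
    ligand_total: float  # uM
    raw_fi: np.ndarray | None = None
    raw_fnorm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.titrant_conc = np.asarray(self.titrant_conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.titrant_conc.ndim != 1 or self.response.shape != self.titrant_conc.shape:
            raise ValidationError("titrant_conc and response must be 1-D and equal length")
        if np.any(self.titrant_conc <= 0):
            raise ValidationError("titrant concentrations must be > 0")
        if np.any(np.diff(self.titrant_conc) <= 0):
            raise ValidationError("titrant concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise ValidationError("responses must be finite")
        if self.ligand_total <= 0:
            raise ValidationError("ligand_total must be > 0")

    def __len__(self) -> int:
        return int(self.titrant_conc.size)


@dataclass
class BindingFitResult:
    kd: float  # uM
    amplitude: float
    offset: float
    residual_sum_of_squares: float
    converged: bool
    ci: dict[str, float] | None = None  # {"kd_low": .., "kd_high": .., "level": ..}

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValidationError("fitted kd must be > 0")
        if self.ci is not None and not (
            self.ci["kd_low"] <= self.kd <= self.ci["kd_high"]
        ):
            raise ValidationError("kd must lie inside its confidence interval")

    def to_json(self) -> str:
        payload = {
            "kd_uM": self.kd,
            "amplitude": self.amplitude,
            "offset": self.offset,
            "rss": self.residual_sum_of_squares,
            "converged": self.converged,
        }
        if self.ci is not None:
            payload["ci"] = self.ci
        return json.dumps(payload, indent=2)


class KdRegressor(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares estimator for the depletion-model dose-response.

    Fits ``response = offset + amplitude * FB(A; B, Kd)`` where ``A`` are the
    titrant concentrations passed as ``X`` and ``B = ligand_total`` is fixed.
    All concentrations (X, ligand_total, kd_) share one unit.

    Parameters
    ----------
    ligand_total : float
        Total concentration of the labelled partner B, same unit as X.
    fit_offset : bool
        Whether to fit a constant baseline (default off: normalized MST
        responses start at 0).
    init_kd : float or None
        Starting Kd.  By default the fit multi-starts from the titrant
        concentration nearest half-maximal response plus a log-spaced grid
        spanning the titrant range and keeps the solution with the lowest
        residual sum of squares: under strong ligand depletion (B >> Kd) the
        objective is bimodal in Kd, with a shallow decoy minimum at large Kd
        that a single half-max start can roll into.  Passing ``init_kd``
        disables the multi-start.
    kd_bounds : (float, float)
        Box constraints on Kd; the lower bound keeps the model analytic at
        kd -> 0.

    Attributes
    ----------
    kd_, amplitude_, offset_ : fitted parameters.
    rss_ : residual sum of squares.
    converged_ : optimizer success flag (a failed fit still exposes its last
        iterate, flagged ``converged_ = False``, never a silent answer).
    """

    def __init__(
        self,
        ligand_total: float = 1.0,
        fit_offset: bool = False,
        init_kd: float | None = None,
        kd_bounds: tuple[float, float] = (1e-6, 1e9),
    ):
        self.ligand_total = ligand_total
        self.fit_offset = fit_offset
        self.init_kd = init_kd
        self.kd_bounds = kd_bounds

    def _model(self, a: np.ndarray, params: np.ndarray) -> np.ndarray:
        kd, amplitude = params[0], params[1]
        offset = params[2] if self.fit_offset else 0.0
        return offset + amplitude * fraction_bound(a, self.ligand_total, kd)

    def fit(self, X, y) -> "KdRegressor":
        a = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if a.size != y.size:
            raise ValidationError("X and y must have equal length")
        if a.size < 5:
            raise ValidationError("need at least 5 dose-response points")
        if self.ligand_total <= 0:
            raise ValidationError("ligand_total must be > 0")
        span = float(np.max(y) - np.min(y))
        if span <= 0 or np.max(np.abs(y)) == 0:
            raise FitError("degenerate flat response; nothing to fit")

        if self.init_kd is not None:
            starts = [float(self.init_kd)]
        else:
            half = np.min(y) + 0.5 * span
            starts = [float(a[int(np.argmin(np.abs(y - half)))])]
            starts.extend(np.geomspace(np.min(a), 10.0 * np.max(a), 7))
        lower = [self.kd_bounds[0], -np.inf]
        upper = [self.kd_bounds[1], np.inf]
        if self.fit_offset:
            lower.append(-np.inf)
            upper.append(np.inf)

        result = None
        for kd0 in starts:
            p0 = [float(np.clip(kd0, *self.kd_bounds)), float(np.max(y))]
            if self.fit_offset:
                p0.append(0.0)
            candidate = least_squares(
                lambda p: self._model(a, p) - y,
                x0=np.asarray(p0),
                bounds=(lower, upper),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if result is None or np.sum(candidate.fun**2) < np.sum(result.fun**2):
                result = candidate
        self.kd_ = float(result.x[0])
        self.amplitude_ = float(result.x[1])
        self.offset_ = float(result.x[2]) if self.fit_offset else 0.0
        self.rss_ = float(np.sum(result.fun**2))
        self.converged_ = bool(result.success)
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        a = np.asarray(X, dtype=float).reshape(-1)
        params = [self.kd_, self.amplitude_]
        if self.fit_offset:
            params.append(self.offset_)
        return self._model(a, np.asarray(params))


def fit_kd(
    data: DoseResponse,
    fit_offset: bool = False,
    init_kd: float | None = None,
    bounds: tuple[float, float] | None = None,
) -> BindingFitResult:
    """Fit Kd (reported in uM) to a dose-response curve held in nM."""
    reg = KdRegressor(
        ligand_total=data.ligand_total * 1000.0,  # uM -> nM
        fit_offset=fit_offset,
        init_kd=init_kd,
        kd_bounds=bounds if bounds is not None else (1e-6, 1e9),
    )
    reg.fit(data.titrant_conc, data.response)
    return BindingFitResult(
        kd=reg.kd_ / 1000.0,
        amplitude=reg.amplitude_,
        offset=reg.offset_,
        residual_sum_of_squares=reg.rss_,
        converged=reg.converged_,
    )


def bootstrap_ci(
    data: DoseResponse,
    fit: BindingFitResult,
    n_boot: int = 500,
    level: float = 0.95,
    seed: int = 0,
    residual_type: str = "relative",
) -> dict[str, float]:
    """Residual-resampling bootstrap percentile interval for Kd (uM).

    ``residual_type="relative"`` (default) resamples relative residuals
    (r_i / yhat_i) and reapplies them multiplicatively, matching the
    signal-proportional error structure of normalized dose-response data;
    with plain additive resampling the near-zero residuals the fit leaves at
    the few high-signal, high-leverage points make the interval far too
    narrow.  ``residual_type="absolute"`` gives the classic additive scheme
    for homoscedastic data.  Deterministic given ``seed``; raises if more
    than 20% of replicate refits fail.
    """
    if not fit.converged:
        raise FitError("cannot bootstrap a non-converged fit")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    if residual_type not in ("relative", "absolute"):
        raise ValidationError("residual_type must be 'relative' or 'absolute'")
    b_nm = data.ligand_total * 1000.0
    fitted = fit.offset + fit.amplitude * fraction_bound(
        data.titrant_conc, b_nm, fit.kd * 1000.0
    )
    residuals = data.response - fitted
    if residual_type == "relative":
        floor = 1e-12 * max(1.0, float(np.max(np.abs(fitted))))
        rel = residuals / np.where(np.abs(fitted) < floor, floor, fitted)
    rng = np.random.default_rng(seed)
    kds = []
    failures = 0
    for _ in range(n_boot):
        if residual_type == "relative":
            resampled = fitted * (
                1.0 + rng.choice(rel, size=rel.size, replace=True)
            )
        else:
            resampled = fitted + rng.choice(residuals, size=residuals.size, replace=True)
        try:
            reg = KdRegressor(ligand_total=b_nm, fit_offset=fit.offset != 0.0,
                              init_kd=fit.kd * 1000.0)
            reg.fit(data.titrant_conc, resampled)
            if not reg.converged_:
                raise FitError("replicate did not converge")
            kds.append(reg.kd_ / 1000.0)
        except (FitError, ValidationError):
            failures += 1
    if failures > 0.2 * n_boot:
        raise FitError(f"bootstrap unstable: {failures}/{n_boot} replicate refits failed")
    lo, hi = np.percentile(kds, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return {"kd_low": float(lo), "kd_high": float(hi), "level": level}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_dose_response(source: str | Path) -> DoseResponse:
    """Read a dose-response CSV: ``# ligand_total_uM = <x>`` metadata lines
    followed by a ``conc_nM,response`` header and data rows."""
    ligand_total = None
    conc, resp = [], []
    with open(source) as handle:
        header_seen = False
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, value = (t.strip() for t in body.split("=", 1))
                    if key == "ligand_total_uM":
                        ligand_total = float(value)
                continue
            if not header_seen:
                if line.replace(" ", "") != "conc_nM,response":
                    raise FormatError(
                        f"{source} line {lineno}: expected header 'conc_nM,response'"
                    )
                header_seen = True
                continue
            fields = line.split(",")
            if len(fields) != 2:
                raise FormatError(f"{source} line {lineno}: expected 2 fields")
            try:
                conc.append(float(fields[0]))
                resp.append(float(fields[1]))
            except ValueError as exc:
                raise FormatError(f"{source} line {lineno}: {exc}") from exc
    if ligand_total is None:
        raise FormatError(f"{source}: missing '# ligand_total_uM = <x>' metadata line")
    return DoseResponse(np.array(conc), np.array(resp), ligand_total=ligand_total)


def write_dose_response(data: DoseResponse, dest: str | Path) -> None:
    with open(dest, "w") as handle:
        handle.write(f"# ligand_total_uM = {data.ligand_total:g}\n")
        handle.write("conc_nM,response\n")
        for c, r in zip(data.titrant_conc, data.response):
            handle.write(f"{c:.6g},{r:.8g}\n")
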