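"""1:1 Langmuir SPR kinetics: sensorgram simulation and global fitting.

The surface reaction A + B <-> AB at analyte concentration C obeys

    dR/dt = kon * C * (Rmax - R) - koff * R        (association)
    dR/dt = -koff * R                              (dissociation)

with closed-form phases

    R(t)  = Req * (1 - exp(-(kon*C + koff) * t)),  Req = Rmax * C / (C + KD)
    R(t') = R0 * exp(-koff * t')

and KD = koff / kon.  Fitting is a global nonlinear least squares across an
injection series sharing (kon, koff, Rmax); an outlier rule excludes (and
reports) injections whose individually fitted plateau
deviates from the global prediction by more than 3x the cross-injection
residual spread.  Mass-transport limitation is deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Injection",
    "Sensorgram",
    "KineticFit",
    "InvalidParameter",
    "FitDivergence",
    "simulate_sensorgram",
    "fit_kinetics",
    "load_long_csv",
    "save_long_csv",
    "load_spr_workbook",
]


class InvalidParameter(ValueError):
    pass


class FitDivergence(RuntimeError):
    pass


@dataclass
class Injection:
    concentration: float  # molar
    times: np.ndarray  # s, from injection start, strictly increasing
    responses: np.ndarray  # RU
    association_end: float  # s; dissociation starts here

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.responses = np.asarray(self.responses, float)
        if self.concentration <= 0:
            raise InvalidParameter("analyte concentration must be > 0")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameter("times must be strictly increasing")


@dataclass
class Sensorgram:
    injections: list
    blank: Optional[np.ndarray] = None  # subtracted response series

    def blank_subtracted(self) -> "Sensorgram":
        if self.blank is None:
            return self
        injs = [
            Injection(i.concentration, i.times,
                      i.responses - self.blank, i.association_end)
            for i in self.injections
        ]
        return Sensorgram(injections=injs)


@dataclass
class KineticFit:
    kon: float  # 1/(M s)
    koff: float  # 1/s
    rmax: float  # RU
    residual_rms: float  # RU
    excluded_injections: list = field(default_factory=list)

    @property
    def kd(self) -> float:
        return self.koff / self.kon


def langmuir_response(
    times: np.ndarray, conc: float, kon: float, koff: float,
    rmax: float, association_end: float,
) -> np.ndarray:
    """Closed-form 1:1 response over one association + dissociation cycle."""
    times = np.asarray(times, float)
    kobs = kon * conc + koff
    kd = koff / kon
    req = rmax * conc / (conc + kd)
    r = np.empty_like(times)
    assoc = times <= association_end
    r[assoc] = req * (1.0 - np.exp(-kobs * times[assoc]))
    r0 = req * (1.0 - np.exp(-kobs * association_end))
    r[~assoc] = r0 * np.exp(-koff * (times[~assoc] - association_end))
    return r


def simulate_sensorgram(
    kon: float,
    koff: float,
    rmax: float,
    concentrations: Sequence[float],
    association_s: float = 120.0,
    dissociation_s: float = 180.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Sensorgram:
    """Simulate an injection series from the closed-form 1:1 model with
    optional i.i.d. Gaussian read noise (RU)."""
    if min(kon, rmax) <= 0 or koff < 0:
        raise InvalidParameter("kon, Rmax must be > 0 and koff >= 0")
    if not concentrations:
        raise InvalidParameter("need at least one concentration")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, association_s + dissociation_s + dt / 2, dt)
    injections = []
    for conc in concentrations:
        if koff == 0.0:
            # limit koff->0: full saturation kinetics with flat dissociation
            kobs = kon * conc
            req = rmax
            r = np.where(
                times <= association_s,
                req * (1.0 - np.exp(-kobs * times)),
                req * (1.0 - np.exp(-kobs * association_s)),
            )
        else:
            r = langmuir_response(times, conc, kon, koff, rmax, association_s)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=r.shape)
        injections.append(Injection(conc, times, r, association_s))
    return Sensorgram(injections=injections)


# ---------------------------------------------------------------------------
# initialization helpers
# ---------------------------------------------------------------------------

def _initial_guess(gram: Sensorgram) -> np.ndarray:
    """(kon, koff, Rmax) start values: koff from a log-linear fit of the
    dissociation tail, kon from the kobs-vs-C line, Rmax from the largest
    plateau scaled by its estimated fractional saturation."""
    inj = max(gram.injections, key=lambda i: i.concentration)
    mask = inj.times > inj.association_end
    t, r = inj.times[mask], inj.responses[mask]
    pos = r > max(1e-9, 0.01 * np.nanmax(np.abs(r)))
    if pos.sum() >= 3:
        slope = np.polyfit(t[pos] - inj.association_end, np.log(r[pos]), 1)[0]
        koff0 = max(1e-5, -slope)
    else:
        koff0 = 1e-3

    kobs_list, conc_list = [], []
    for i in gram.injections:
        am = i.times <= i.association_end
        ra = i.responses[am]
        req = ra[-1] if len(ra) else 0.0
        if req <= 0:
            continue
        # time to reach half the plateau ~ ln 2 / kobs
        above = np.nonzero(ra >= 0.5 * req)[0]
        if len(above) and i.times[am][above[0]] > 0:
            kobs_list.append(np.log(2.0) / i.times[am][above[0]])
            conc_list.append(i.concentration)
    if len(kobs_list) >= 2:
        kon0 = max(1e1, np.polyfit(conc_list, kobs_list, 1)[0])
    else:
        kon0 = 1e4
    kd0 = koff0 / kon0
    cmax = inj.concentration
    req_max = float(np.max(inj.responses))
    rmax0 = max(req_max, req_max * (cmax + kd0) / cmax)
    return np.array([kon0, koff0, rmax0])


def _global_residuals(log_params: np.ndarray, injections: list) -> np.ndarray:
    kon, koff, rmax = np.exp(log_params)
    res = []
    for inj in injections:
        model = langmuir_response(
            inj.times, inj.concentration, kon, koff, rmax, inj.association_end
        )
        res.append(inj.responses - model)
    return np.concatenate(res)


def _fit_once(injections: list, x0: np.ndarray) -> tuple[np.ndarray, float]:
    sol = least_squares(
        _global_residuals, np.log(x0), args=(injections,),
        method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000,
    )
    if not sol.success and not np.isfinite(sol.cost):
        raise FitDivergence(sol.message)
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return np.exp(sol.x), rms


def fit_kinetics(
    gram: Sensorgram,
    init: Optional[Sequence[float]] = None,
    exclude_outliers: bool = True,
) -> KineticFit:
    """Global 1:1 fit of an injection series sharing (kon, koff, Rmax).

    Requires >= 3 injections at distinct concentrations.  With
    ``exclude_outliers`` an outlier rule drops injections whose
    individually fitted plateau Req deviates from the global prediction by
    > 3x the cross-injection deviation spread, refits, and reports them.
    """
    gram = gram.blank_subtracted()
    injections = list(gram.injections)
    if len({i.concentration for i in injections}) < 3:
        raise InvalidParameter("need >= 3 injections at distinct concentrations")
    x0 = np.asarray(init, float) if init is not None else _initial_guess(gram)

    try:
        params, rms = _fit_once(injections, x0)
    except FitDivergence:
        params, rms = _fit_once(injections, np.array([1e4, 0.01, 100.0]))

    excluded: list = []
    if exclude_outliers and len(injections) > 3:
        kon, koff, rmax = params
        kd = koff / kon
        devs = []
        for inj in injections:
            kobs = kon * inj.concentration + koff
            am = inj.times <= inj.association_end
            shape = 1.0 - np.exp(-kobs * inj.times[am])
            denom = float(shape @ shape)
            req_alone = float(shape @ inj.responses[am]) / denom if denom else 0.0
            req_pred = rmax * inj.concentration / (inj.concentration + kd)
            devs.append(req_alone - req_pred)
        devs = np.asarray(devs)
        # robust spread (1.4826*MAD ~ sd under normality) so a single
        # anomalous injection cannot mask itself
        spread = 1.4826 * float(np.median(np.abs(devs - np.median(devs))))
        if spread == 0.0:
            spread = float(np.std(devs, ddof=1))
        if spread > 0:
            # centered on the median: the outlier biases the global fit,
            # shifting every deviation by a common offset
            bad = np.abs(devs - np.median(devs)) > 3.0 * spread
            if bad.any() and (~bad).sum() >= 3:
                excluded = [i for i, b in enumerate(bad) if b]
                kept = [inj for inj, b in zip(injections, bad) if not b]
                params, rms = _fit_once(kept, params)

    kon, koff, rmax = params
    return KineticFit(
        kon=float(kon), koff=float(koff), rmax=float(rmax),
        residual_rms=rms, excluded_injections=excluded,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_long_csv(path: str) -> Sensorgram:
    """Long-format CSV: injection_id, phase (association|dissociation),
    time_s, response_RU, conc_M."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"injection_id", "phase", "time_s", "response_RU", "conc_M"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    injections = []
    for _, grp in df.groupby("injection_id", sort=True):
        grp = grp.sort_values("time_s")
        assoc = grp[grp["phase"] == "association"]
        a_end = float(assoc["time_s"].max()) if len(assoc) else 0.0
        injections.append(
            Injection(
                concentration=float(grp["conc_M"].iloc[0]),
                times=grp["time_s"].to_numpy(),
                responses=grp["response_RU"].to_numpy(),
                association_end=a_end,
            )
        )
    return Sensorgram(injections=injections)


def save_long_csv(gram: Sensorgram, path: str) -> None:
    import pandas as pd

    rows = []
    for k, inj in enumerate(gram.injections):
        for t, r in zip(inj.times, inj.responses):
            rows.append(
                {
                    "injection_id": k,
                    "phase": "association" if t <= inj.association_end
                    else "dissociation",
                    "time_s": t,
                    "response_RU": r,
                    "conc_M": inj.concentration,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_spr_workbook(
    path: str,
    sheet: object = 0,
    association_end: Optional[float] = None,
) -> Sensorgram:
    """Import a reference-corrected SPR workbook laid out as repeated
    (time, response) column pairs per injection, with analyte molarity in
    the header of each response column (e.g. "2.0 uM").  The corrected
    series (sample minus reference channel) is expected; no further blank
    subtraction is applied."""
    import re

    import pandas as pd

    df = pd.read_excel(path, sheet_name=sheet)
    cols = list(df.columns)
    injections = []
    for i in range(0, len(cols) - 1, 2):
        tcol, rcol = cols[i], cols[i + 1]
        m = re.search(r"([\d.]+)\s*([munp]?)M", str(rcol))
        if not m:
            continue
        scale = {"": 1.0, "m": 1e-3, "u": 1e-6, "n": 1e-9, "p": 1e-12}[m.group(2)]
        conc = float(m.group(1)) * scale
        sub = df[[tcol, rcol]].dropna()
        t = sub[tcol].to_numpy(float)
        r = sub[rcol].to_numpy(float)
        t = t - t[0]
        a_end = association_end if association_end is not None else float(
            t[np.argmax(r)]
        )
        injections.append(Injection(conc, t, r, a_end))
    if not injections:
        raise ValueError("no (time, response) injection column pairs found")
    return Sensorgram(injections=injections)
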