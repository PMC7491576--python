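"""Tautomer-resolved titration analysis for a three-state histidine.

Microscopic model
-----------------
The doubly protonated imidazolium (HIP, +1) loses either its N-delta proton
(microscopic constant pKa_delta, giving HIE) or its N-epsilon proton
(pKa_epsilon, giving HID).  With [H+] = 10^-pH, Ka_d = 10^-pKa_delta and
Ka_e = 10^-pKa_epsilon, the equilibrium populations are proportional to

    f_HIP : f_HID : f_HIE  =  [H+] : Ka_e : Ka_d

(HID retains the N-delta proton, so its population carries the constant for
*losing the other* proton).  The macroscopic constant for the +1 -> 0
transition sums the microscopic ones:

    pKa_macro = -log10(Ka_d + Ka_e)

Macroscopic analysis fits the deprotonated (neutral) fraction
S = f_HID + f_HIE with the generalized Hill curve
S(pH) = 1 / (1 + 10^(n (pKa - pH))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigError, DataError

STATES = ("HID", "HIE", "HIP")


@dataclass(frozen=True)
class MicroTautomerModel:
    """Microscopic two-site histidine model.

    pka_delta: pKa for loss of the N-delta proton (HIP -> HIE).
    pka_epsilon: pKa for loss of the N-epsilon proton (HIP -> HID).
    A one-site (e.g. carboxylic acid) titration is the degenerate case
    pka_epsilon = +inf handled by :func:`micro_populations` limits.
    """

    pka_delta: float
    pka_epsilon: float

    def __post_init__(self):
        if np.isnan(self.pka_delta) or np.isnan(self.pka_epsilon):
            raise ConfigError("microscopic pKa values must not be NaN")


def micro_populations(model: MicroTautomerModel, ph):
    """(f_HIP, f_HID, f_HIE) at the given pH (scalar or array)."""
    ph = np.asarray(ph, dtype=float)
    # exponents of [H+], Ka_epsilon, Ka_delta; shift by the running maximum
    # so the weights stay finite (an infinite pKa gives weight 0: the
    # degenerate one-site model)
    e_hip, e_hid, e_hie = -ph, -model.pka_epsilon, -model.pka_delta
    m = np.maximum(e_hip, max(e_hid, e_hie))
    w_hip = 10.0 ** (e_hip - m)
    w_hid = 10.0 ** (np.minimum(e_hid - m, 0.0))
    w_hie = 10.0 ** (np.minimum(e_hie - m, 0.0))
    total = w_hip + w_hid + w_hie
    return w_hip / total, w_hid / total, w_hie / total


def macro_pka(model: MicroTautomerModel) -> float:
    """Macroscopic pKa of the +1 -> 0 transition:
    -log10(10^-pKa_delta + 10^-pKa_epsilon)."""
    lo = min(model.pka_delta, model.pka_epsilon)
    # factor out the dominant constant for numerical stability
    return float(lo - np.log10(1.0 + 10.0 ** (lo - max(model.pka_delta,
                                                       model.pka_epsilon))))


@dataclass
class TitrationCurve:
    """Per-pH tautomer occupancies and deprotonated fraction S."""

    table: pd.DataFrame  # columns: ph, f_hid, f_hie, f_hip, S, n_frames

    def __post_init__(self):
        t = self.table
        total = t[["f_hid", "f_hie", "f_hip"]].sum(axis=1)
        if not np.allclose(total, 1.0, atol=1e-12):
            raise DataError("occupancies do not sum to 1")


@dataclass
class PkaFit:
    pka: float
    hill_n: float
    residual: float
    converged: bool
    extrapolated: bool = False


def occupancies(records: pd.DataFrame) -> TitrationCurve:
    """Per-pH state frequencies from a (ph, frame, state[, distance]) table."""
    if records.empty:
        raise DataError("no titration records")
    bad = set(records["state"].unique()) - set(STATES)
    if bad:
        raise DataError(f"unknown state token(s): {sorted(bad)}")
    rows = []
    for ph, grp in records.groupby("ph", sort=True):
        n = len(grp)
        counts = grp["state"].value_counts()
        f_hid = counts.get("HID", 0) / n
        f_hie = counts.get("HIE", 0) / n
        f_hip = counts.get("HIP", 0) / n
        rows.append({"ph": float(ph), "f_hid": f_hid, "f_hie": f_hie,
                     "f_hip": f_hip, "S": f_hid + f_hie, "n_frames": n})
    return TitrationCurve(table=pd.DataFrame(rows))


def hill_curve(ph, pka, n):
    """Deprotonated fraction of the generalized single-site Hill model."""
    return 1.0 / (1.0 + 10.0 ** (n * (pka - ph)))


def fit_hill(curve: TitrationCurve, fix_n: float | None = None) -> PkaFit:
    """Least-squares Hill fit of S(pH).

    Deterministic: initialized at pKa0 = pH of the point with S nearest 0.5
    and n0 = 1.  Requires >= 4 pH points (>= 2 if n is fixed) and S samples
    on both sides of 0.5 for a non-extrapolated estimate.
    """
    t = curve.table.sort_values("ph")
    ph = t["ph"].to_numpy(dtype=float)
    S = t["S"].to_numpy(dtype=float)
    min_pts = 2 if fix_n is not None else 4
    if len(ph) < min_pts:
        raise DataError(f"need >= {min_pts} pH points, have {len(ph)}")
    if np.allclose(S, S[0]):
        raise DataError("degenerate titration data: S constant across pH")
    pka0 = float(ph[np.argmin(np.abs(S - 0.5))])
    try:
        if fix_n is None:
            popt, _ = curve_fit(hill_curve, ph, S, p0=(pka0, 1.0), maxfev=10000)
            pka, n = float(popt[0]), float(popt[1])
        else:
            popt, _ = curve_fit(lambda x, p: hill_curve(x, p, fix_n), ph, S,
                                p0=(pka0,), maxfev=10000)
            pka, n = float(popt[0]), float(fix_n)
    except RuntimeError as exc:
        raise DataError(f"Hill fit did not converge: {exc}") from exc
    resid = float(np.linalg.norm(hill_curve(ph, pka, n) - S))
    extrapolated = not (ph.min() - 2.0 <= pka <= ph.max() + 2.0) \
        or not (S.min() < 0.5 < S.max())
    return PkaFit(pka=pka, hill_n=n, residual=resid, converged=True,
                  extrapolated=extrapolated)


def state_conditional_distances(records: pd.DataFrame) -> pd.DataFrame:
    """Per (pH, state): mean ligand distance and that state's occupancy.

    States with zero records at a pH are omitted; records lacking a distance
    are excluded from the mean but counted in the occupancy.
    """
    if "distance" not in records or records["distance"].isna().all():
        raise DataError("no distances in any record")
    rows = []
    for ph, grp in records.groupby("ph", sort=True):
        n = len(grp)
        for state, sgrp in grp.groupby("state", sort=True):
            rows.append({
                "ph": float(ph),
                "state": state,
                "mean_distance": float(sgrp["distance"].mean()),
                "occupancy": len(sgrp) / n,
            })
    return pd.DataFrame(rows)


def coupling_exclusivity(records: pd.DataFrame,
                         lock_cutoff: float = 4.0) -> float | None:
    """Fraction of records with distance < lock_cutoff that are HID.

    1.0 means the short-distance regime exclusively samples HID.  Returns
    None (missing) when no record falls below the cutoff.
    """
    if "distance" not in records:
        raise DataError("records carry no distances")
    below = records[records["distance"] < lock_cutoff]
    if below.empty:
        return None
    return float((below["state"] == "HID").mean())


def pka_convergence(records: pd.DataFrame, n_chunks: int = 5,
                    tol: float = 0.1, fix_n: float | None = None) -> pd.DataFrame:
    """Hill-fit pKa on growing prefixes of the (time-ordered) record stream.

    Chunk k uses the first k/n_chunks of frames at every pH.  The run is
    declared converged when the last two estimates differ by < ``tol``.
    Returns a table (fraction, pka, converged) where ``converged`` is set on
    the final row.
    """
    if n_chunks < 2:
        raise ConfigError("need at least 2 chunks")
    records = records.sort_values(["ph", "frame"])
    estimates = []
    for k in range(1, n_chunks + 1):
        frac = k / n_chunks
        parts = [g.iloc[: max(1, int(np.floor(len(g) * frac)))]
                 for _, g in records.groupby("ph", sort=True)]
        fit = fit_hill(occupancies(pd.concat(parts)), fix_n=fix_n)
        estimates.append({"fraction": frac, "pka": fit.pka})
    out = pd.DataFrame(estimates)
    out["converged"] = False
    out.loc[out.index[-1], "converged"] = bool(
        abs(out["pka"].iloc[-1] - out["pka"].iloc[-2]) < tol
    )
    return out
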