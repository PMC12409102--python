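"""Lake-model fluorescence algebra for steady-state PAM measurements.

Converts raw steady-state fluorescence parameters (Fs, Fm', Fo') into the
regulatory state of photosystem II (qL, NPQt) and the three quantum yields
that partition absorbed light energy:

* ``phi_psii`` — quantum yield of PSII photochemistry, (Fm' − Fs)/Fm';
* ``phi_no``   — quantum yield of nonregulated losses (basal heat dissipation
  plus fluorescence re-emission), 1/(1 + 4.88·qL + NPQt);
* ``phi_npq``  — quantum yield of regulated heat dissipation, the remainder
  1 − ΦPSII − ΦNO.

NPQt is the dark-adaptation-free estimate of nonphotochemical quenching,
NPQt = 4.88/((Fm'/Fo') − 1) − 1, built on an assumed dark-adapted Fm/Fo of
5.88 (i.e. Fv/Fm ≈ 0.83); qL is the fraction of open PSII reaction centers
under the lake (connected-antenna) model,
qL = ((Fm' − Fs)/(Fm' − Fo'))·(Fo'/Fs).

The module also provides the exact inverse mapping (:func:`forward_fluorescence`)
from a (qL, NPQt) state to (Fs, Fm', Fo') under the same convention, which the
synthetic generator uses and which serves as a round-trip oracle, plus the QC
filter used on field tables (all three yields positive, summing to one) and a
Tetens-based vapor-pressure-deficit derivation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FM_FO_DARK",
    "K_DARK",
    "PhotoState",
    "YieldTriple",
    "InvalidMeasurementError",
    "compute_npqt",
    "compute_ql",
    "compute_phi_no",
    "compute_phi_psii",
    "compute_phi_npq",
    "forward_fluorescence",
    "derive_vpd",
    "add_yields",
    "qc_filter",
]

#: Assumed dark-adapted Fm/Fo ratio underlying the NPQt convention.
FM_FO_DARK = 5.88
#: The constant 4.88 = FM_FO_DARK − 1 (equivalently the dark Fv/Fo).
K_DARK = FM_FO_DARK - 1.0

#: Default column names for tabular input/output.
DEFAULT_COLUMNS = dict(
    fs="fs", fm_prime="fm_prime", fo_prime="fo_prime", par="par",
    air_temp="air_temp", rh="rh", vpd="vpd", height="height_m",
    species="species", season="season", tree_id="tree_id",
    branch_position="branch_position", leaf_id="leaf_id",
)


class InvalidMeasurementError(ValueError):
    """Raised when fluorescence parameters are physically impossible."""


@dataclass(frozen=True)
class PhotoState:
    """Lake-model regulatory state of PSII: open-center fraction and NPQt.

    Fields may be scalars or numpy arrays.
    """

    ql: float | np.ndarray
    npqt: float | np.ndarray

    def __post_init__(self) -> None:
        ql = np.asarray(self.ql, dtype=float)
        npqt = np.asarray(self.npqt, dtype=float)
        if np.any(ql < 0) or np.any(ql > 1):
            raise ValueError("ql must lie in [0, 1]")
        if np.any(npqt < 0):
            raise ValueError("npqt must be >= 0")


@dataclass(frozen=True)
class YieldTriple:
    """The three quantum yields; they partition unity exactly."""

    phi_psii: float | np.ndarray
    phi_no: float | np.ndarray
    phi_npq: float | np.ndarray

    def is_valid(self, tol: float = 1e-6) -> bool | np.ndarray:
        s = np.asarray(self.phi_psii) + np.asarray(self.phi_no) + np.asarray(self.phi_npq)
        pos = (np.asarray(self.phi_psii) > 0) & (np.asarray(self.phi_no) > 0) & (
            np.asarray(self.phi_npq) > 0
        )
        return pos & (np.abs(s - 1.0) <= tol)


def compute_npqt(fm_prime, fo_prime, k: float = K_DARK):
    """Dark-adaptation-free NPQ estimate, ``k/((Fm'/Fo') − 1) − 1``.

    Equals 0 exactly when Fm'/Fo' matches the assumed dark ratio ``k + 1``
    and grows without bound as the ratio approaches 1 (complete quenching of
    variable fluorescence).
    """
    fm_prime = np.asarray(fm_prime, dtype=float)
    fo_prime = np.asarray(fo_prime, dtype=float)
    if np.any(fm_prime <= 0) or np.any(fo_prime <= 0):
        raise ValueError("fluorescence yields must be positive")
    ratio = fm_prime / fo_prime
    if np.any(ratio <= 1):
        raise InvalidMeasurementError("Fm'/Fo' must exceed 1")
    out = k / (ratio - 1.0) - 1.0
    return out if out.ndim else float(out)


def compute_ql(fs, fm_prime, fo_prime):
    """Fraction of open PSII centers, ``((Fm'−Fs)/(Fm'−Fo'))·(Fo'/Fs)``.

    Lies in [0, 1] whenever Fo' ≤ Fs ≤ Fm'; values outside that band are
    returned as-is (the QC filter, not this function, rejects them).
    """
    fs = np.asarray(fs, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    fo_prime = np.asarray(fo_prime, dtype=float)
    if np.any(fm_prime <= fo_prime):
        raise InvalidMeasurementError("Fm' must exceed Fo'")
    if np.any(fs <= 0):
        raise ValueError("Fs must be positive")
    out = (fm_prime - fs) / (fm_prime - fo_prime) * (fo_prime / fs)
    return out if out.ndim else float(out)


def compute_phi_no(photo_state: PhotoState, k: float = K_DARK):
    """Quantum yield of nonregulated losses, ``1/(1 + k·qL + NPQt)``."""
    ql = np.asarray(photo_state.ql, dtype=float)
    npqt = np.asarray(photo_state.npqt, dtype=float)
    out = 1.0 / (1.0 + k * ql + npqt)
    return out if out.ndim else float(out)


def compute_phi_psii(fs, fm_prime):
    """Quantum yield of PSII photochemistry, ``(Fm' − Fs)/Fm'``."""
    fs = np.asarray(fs, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    if np.any(fm_prime <= 0):
        raise ValueError("Fm' must be positive")
    out = (fm_prime - fs) / fm_prime
    return out if out.ndim else float(out)


def compute_phi_npq(phi_psii, phi_no):
    """Regulated-quenching yield as the exact remainder ``1 − ΦPSII − ΦNO``.

    May come out nonpositive for noisy raw data; such records are data for
    :func:`qc_filter`, not an error here.
    """
    out = 1.0 - np.asarray(phi_psii, dtype=float) - np.asarray(phi_no, dtype=float)
    return out if out.ndim else float(out)


def forward_fluorescence(photo_state: PhotoState, fo_dark: float = 1.0,
                         k: float = K_DARK):
    """Exact inverse model: map (qL, NPQt) to (Fs, Fm', Fo').

    Normalises the dark-adapted state to Fo = ``fo_dark``, Fm = ``(k+1)·fo_dark``.
    Fm' follows from the NPQt definition, Fo' from the Oxborough–Baker relation
    ``1/Fo' = 1/Fo − 1/Fm + 1/Fm'``, and Fs from the qL definition:
    ``Fs = A·Fm'/(qL + A)`` with ``A = Fo'/(Fm' − Fo') = (1 + NPQt)/k``.

    Running :func:`compute_npqt` and :func:`compute_ql` on the output recovers
    the inputs to machine precision, which makes this the round-trip oracle for
    the whole algebra and the raw-signal model of the synthetic generator.
    """
    ql = np.asarray(photo_state.ql, dtype=float)
    npqt = np.asarray(photo_state.npqt, dtype=float)
    fm_dark = (k + 1.0) * fo_dark
    fm_prime = fm_dark / (1.0 + npqt)
    fo_prime = 1.0 / (1.0 / fo_dark - 1.0 / fm_dark + 1.0 / fm_prime)
    a = fo_prime / (fm_prime - fo_prime)
    fs = a * fm_prime / (ql + a)
    if fs.ndim:
        return fs, fm_prime + np.zeros_like(fs), fo_prime + np.zeros_like(fs)
    return float(fs), float(fm_prime), float(fo_prime)


def derive_vpd(air_temp, rh):
    """Vapor pressure deficit (kPa) from air temperature (°C) and RH (%).

    Uses the Tetens saturation vapor pressure
    ``e_s = 0.61078·exp(17.27·T/(T + 237.3))`` and ``VPD = e_s·(1 − RH/100)``.
    """
    air_temp = np.asarray(air_temp, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity must lie in [0, 100]")
    es = 0.61078 * np.exp(17.27 * air_temp / (air_temp + 237.3))
    out = es * (1.0 - rh / 100.0)
    return out if out.ndim else float(out)


def add_yields(df: pd.DataFrame, columns: Mapping[str, str] | None = None,
               k: float = K_DARK, recompute: bool = False,
               discrepancy_tol: float = 1e-3) -> pd.DataFrame:
    """Append npqt/ql/phi_psii/phi_no/phi_npq columns to a measurement table.

    If the table already carries yield columns (as MultispeQ exports do) they
    are kept and only cross-validated against the raw-signal recomputation,
    warning when discrepancies exceed ``discrepancy_tol``; pass
    ``recompute=True`` to overwrite from the raw signals. Rows whose raw
    signals are unusable (Fm' ≤ Fo', nonpositive values) get NaN yields and
    fall to the QC filter.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    out = df.copy()

    fs = out[cols["fs"]].to_numpy(dtype=float)
    fm = out[cols["fm_prime"]].to_numpy(dtype=float)
    fo = out[cols["fo_prime"]].to_numpy(dtype=float)

    usable = (fs > 0) & (fo > 0) & (fm > fo)
    npqt = np.full(len(out), np.nan)
    ql = np.full(len(out), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        npqt[usable] = k / (fm[usable] / fo[usable] - 1.0) - 1.0
        ql[usable] = ((fm[usable] - fs[usable]) / (fm[usable] - fo[usable])
                      * (fo[usable] / fs[usable]))
    phi_psii = np.where(usable, (fm - fs) / np.where(fm > 0, fm, np.nan), np.nan)
    phi_no = 1.0 / (1.0 + k * ql + npqt)
    phi_npq = 1.0 - phi_psii - phi_no

    supplied = [c for c in ("phi_psii", "phi_no", "phi_npq") if c in out.columns]
    if supplied and not recompute:
        for name, calc in (("phi_psii", phi_psii), ("phi_no", phi_no),
                           ("phi_npq", phi_npq)):
            if name in out.columns:
                have = out[name].to_numpy(dtype=float)
                bad = np.isfinite(have) & np.isfinite(calc) & (
                    np.abs(have - calc) > discrepancy_tol)
                if bad.any():
                    warnings.warn(
                        f"{bad.sum()} supplied {name} values differ from the "
                        f"raw-signal recomputation by more than {discrepancy_tol}",
                        stacklevel=2,
                    )
        out["npqt"] = out.get("npqt", pd.Series(npqt, index=out.index))
        out["ql"] = out.get("ql", pd.Series(ql, index=out.index))
    else:
        out["npqt"] = npqt
        out["ql"] = ql
        out["phi_psii"] = phi_psii
        out["phi_no"] = phi_no
        out["phi_npq"] = phi_npq

    if cols["vpd"] not in out.columns or out[cols["vpd"]].isna().all():
        out[cols["vpd"]] = derive_vpd(out[cols["air_temp"]].to_numpy(dtype=float),
                                      out[cols["rh"]].to_numpy(dtype=float))
    return out


def qc_filter(df: pd.DataFrame, tol: float = 1e-6):
    """Keep records whose yields are all positive and sum to one.

    Mirrors the field-data exclusion of noisy raw measurements: a record passes
    only if ΦPSII, ΦNO and ΦNPQ are each > 0 and their sum is within ``tol``
    of 1 (the sum is exact by construction when the yields were computed here,
    so positivity is the active rule; ``tol`` matters for externally supplied
    yields). Returns ``(kept, rejection_log)`` where the log counts rejections
    per rule; the input order is preserved and ``qc_pass``/``qc_reason``
    columns are added to the returned kept frame's source copy.
    """
    needed = ("phi_psii", "phi_no", "phi_npq")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise KeyError(f"yield columns missing: {missing} (run add_yields first)")

    p = df["phi_psii"].to_numpy(dtype=float)
    n = df["phi_no"].to_numpy(dtype=float)
    q = df["phi_npq"].to_numpy(dtype=float)
    s = p + n + q

    finite = np.isfinite(p) & np.isfinite(n) & np.isfinite(q)
    rules = {
        "nonfinite_yield": ~finite,
        "nonpositive_phi_psii": finite & (p <= 0),
        "nonpositive_phi_no": finite & (n <= 0),
        "nonpositive_phi_npq": finite & (q <= 0),
        "sum_not_unity": finite & (np.abs(s - 1.0) > tol),
    }
    reason = np.full(len(df), "", dtype=object)
    for name, mask in rules.items():
        hit = mask & (reason == "")
        reason[hit] = name
    passed = reason == ""

    out = df.copy()
    out["qc_pass"] = passed
    out["qc_reason"] = reason
    log = {name: int(mask.sum()) for name, mask in rules.items()}
    log["n_input"] = int(len(df))
    log["n_kept"] = int(passed.sum())
    log["n_rejected"] = int((~passed).sum())
    if log["n_kept"] == 0 and len(df):
        warnings.warn("qc_filter rejected every record", stacklevel=2)
    return out[passed].copy(), log
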