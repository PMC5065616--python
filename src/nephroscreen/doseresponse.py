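"""Dose-response modelling: log2-ratios, log-logistic fits, and the Dmax matrix.

Each feature's treated/vehicle log2-ratio (Delta) over the tested dose grid is
fitted with the standard 4-parameter log-logistic curve

    Delta(x) = c + (d - c) / (1 + exp(b * (log x - log e)))

on molar concentration x, where c and d are the lower and upper limits, e is
the concentration of half-maximal response and b the relative slope around e.
The per-curve readout Dmax is the fitted response at the fixed reference
concentration of 5 mM (around the highest tested concentration for most
compounds), and the features x compounds Dmax matrix takes the median over
biological replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: reference concentration at which Dmax is read off the fitted curve (mol/L)
REFERENCE_MOLAR = 5e-3


def log_logistic(x, b, c, d, e):
    """4-parameter log-logistic response at concentration ``x`` (mol/L)."""
    x = np.asarray(x, dtype=np.float64)
    return c + (d - c) / (1.0 + np.exp(b * (np.log(x) - np.log(e))))


def log2_ratio(treated, vehicle):
    """Delta = log2(treated / vehicle); the vehicle level must be positive."""
    vehicle = np.asarray(vehicle, dtype=np.float64)
    treated = np.asarray(treated, dtype=np.float64)
    if np.any(vehicle <= 0):
        raise ValueError("vehicle-control value must be positive to form a log2-ratio")
    return np.log2(treated / vehicle)


def ug_per_ml_to_molar(dose_ug_per_ml, molecular_mass):
    """Convert a ug/mL dose to mol/L given the molecular mass in g/mol."""
    if molecular_mass is None or not np.all(np.asarray(molecular_mass) > 0):
        raise ValueError("molecular mass must be a positive number of g/mol")
    return np.asarray(dose_ug_per_ml, dtype=np.float64) / (1000.0 * np.asarray(molecular_mass))


def molar_to_ug_per_ml(molar, molecular_mass):
    """Inverse of :func:`ug_per_ml_to_molar`."""
    return np.asarray(molar, dtype=np.float64) * 1000.0 * np.asarray(molecular_mass)


@dataclass
class DoseResponseCurve:
    """Fitted log-logistic parameters and diagnostics."""

    b: float
    c: float
    d: float
    e: float
    converged: bool
    residual: float
    max_tested_molar: float
    observed_at_top: float  # Delta at the highest tested dose (fallback readout)

    def predict(self, x):
        return log_logistic(x, self.b, self.c, self.d, self.e)


def fit_log_logistic(concentrations, deltas) -> DoseResponseCurve:
    """Nonlinear least-squares fit of the 4-parameter log-logistic model.

    Starts from c0/d0 = min/max of the responses, e0 = geometric mean of the
    concentration range, and tries both slope signs, keeping the better fit.
    log(e) is the free parameter so e stays positive.
    """
    x = np.asarray(concentrations, dtype=np.float64)
    y = np.asarray(deltas, dtype=np.float64)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("concentrations and responses must be 1-D and aligned")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct concentrations to fit 4 parameters")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")

    top_idx = int(np.argmax(x))
    observed_at_top = float(y[top_idx])
    log_x = np.log(x)

    def residuals(theta):
        b, c, d, log_e = theta
        return c + (d - c) / (1.0 + np.exp(b * (log_x - log_e))) - y

    c0, d0 = float(y.min()), float(y.max())
    log_e0 = float(log_x.mean())
    best = None
    for b0 in (1.0, -1.0):
        try:
            # flat/noise-only series make e unidentifiable and stall the
            # optimizer; a tight evaluation budget keeps those cheap (they
            # take the documented fallback path)
            sol = least_squares(residuals, x0=[b0, c0, d0, log_e0],
                                method="lm", max_nfev=500)
        except Exception:  # pragma: no cover - optimizer hard failure
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success or not np.all(np.isfinite(best.x)):
        logger.warning("log-logistic fit failed to converge; fallback Dmax will be used")
        return DoseResponseCurve(b=np.nan, c=np.nan, d=np.nan, e=np.nan,
                                 converged=False, residual=np.nan,
                                 max_tested_molar=float(x.max()),
                                 observed_at_top=observed_at_top)
    b, c, d, log_e = best.x
    return DoseResponseCurve(b=float(b), c=float(c), d=float(d), e=float(np.exp(log_e)),
                             converged=True, residual=float(np.sqrt(2 * best.cost)),
                             max_tested_molar=float(x.max()),
                             observed_at_top=observed_at_top)


def delta_max(curve: DoseResponseCurve, reference: float = REFERENCE_MOLAR,
              ) -> tuple[float, bool]:
    """Dmax = fitted response at the reference concentration (default 5 mM).

    Returns ``(value, extrapolated)``; when the fit did not converge the
    observed response at the highest tested dose is used instead, and
    ``extrapolated`` flags reference concentrations above the tested range.
    """
    extrapolated = reference > curve.max_tested_molar
    if not curve.converged:
        return curve.observed_at_top, extrapolated
    return float(curve.predict(reference)), extrapolated


def assemble_matrix(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Median-over-replicates Dmax matrix (features x compounds).

    ``per_replicate`` must have columns ``feature``, ``compound``,
    ``replicate`` and ``dmax``.  Missing feature x compound combinations are
    an error listing the offending entries.
    """
    required = {"feature", "compound", "replicate", "dmax"}
    if not required.issubset(per_replicate.columns):
        raise ValueError(f"expected columns {sorted(required)}")
    matrix = per_replicate.pivot_table(index="feature", columns="compound",
                                       values="dmax", aggfunc="median")
    if matrix.isna().any().any():
        missing = [(f, c) for f, c in zip(*np.where(matrix.isna().values))]
        raise ValueError(f"missing Dmax entries for {len(missing)} feature/compound pairs")
    return matrix


def compute_dmax_matrix(panel: pd.DataFrame, compounds: pd.DataFrame,
                        reference: float = REFERENCE_MOLAR,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full raw-panel -> Dmax pipeline.

    ``panel`` is a per-condition aggregate table with columns ``compound``,
    ``dose_ug_per_ml``, ``replicate``, ``vehicle_flag`` and one column per
    feature; vehicle rows carry the solvent name in ``compound``.
    ``compounds`` is the metadata table indexed by compound with columns
    ``molecular_mass``, ``solvent`` (and typically ``label``).  Each
    compound's Deltas use the vehicle control matching its solvent and
    replicate.  Returns ``(matrix, provenance)`` where provenance records
    per-curve convergence and extrapolation flags.
    """
    meta_cols = ["compound", "dose_ug_per_ml", "replicate", "vehicle_flag"]
    features = [c for c in panel.columns if c not in meta_cols]
    vehicles = panel[panel["vehicle_flag"]]
    treated = panel[~panel["vehicle_flag"]]

    records = []
    prov = []
    for (compound, replicate), block in treated.groupby(["compound", "replicate"], sort=False):
        if compound not in compounds.index:
            raise ValueError(f"no metadata for compound {compound!r}")
        mass = compounds.loc[compound, "molecular_mass"]
        solvent = compounds.loc[compound, "solvent"]
        control = vehicles[(vehicles["compound"] == solvent)
                           & (vehicles["replicate"] == replicate)]
        if len(control) != 1:
            raise ValueError(
                f"expected one {solvent!r} vehicle row for replicate {replicate}, "
                f"found {len(control)}")
        conc = ug_per_ml_to_molar(block["dose_ug_per_ml"].to_numpy(), mass)
        for feature in features:
            deltas = log2_ratio(block[feature].to_numpy(),
                                control[feature].to_numpy()[0])
            curve = fit_log_logistic(conc, deltas)
            value, extrapolated = delta_max(curve, reference)
            records.append({"feature": feature, "compound": compound,
                            "replicate": replicate, "dmax": value})
            prov.append({"feature": feature, "compound": compound,
                         "replicate": replicate, "converged": curve.converged,
                         "extrapolated": extrapolated})
    per_replicate = pd.DataFrame(records)
    matrix = assemble_matrix(per_replicate)
    # keep the catalog's feature order rather than the pivot's alphabetical one
    matrix = matrix.reindex([f for f in features if f in matrix.index])
    return matrix, pd.DataFrame(prov)
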