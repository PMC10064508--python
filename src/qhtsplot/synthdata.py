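"""Synthetic qHTS dataset generator with known ground truth.

Emulates the structure of a real screening export: an 11-point
titration over 5 log units of concentration, a mixture of active and
inactive compounds, gain- and loss-of-signal responses, one record per
(compound, readout) with coincidence readouts (FLuc/NLuc by default)
sharing each compound's true curve but carrying independent noise, and
opaque annotation columns (compound name, SMILES).

Active compounds draw a Hill curve with the AC50 placed inside the
tested range (shrunk half a log unit from each end), Hill slope
uniform in [0.5, 3], zero-concentration asymptote near 0 % (responses
are normalized), and efficacy magnitude uniform in [50, 100] % with the
sign set by the gain/loss draw.  Responses are the noiseless curve plus
additive Gaussian noise; inactive compounds are pure noise around 0 %.

A single seed drives every draw, so the same spec reproduces the same
dataset (and byte-identical written files).  ``fit_hill`` is the
recovery oracle: a least-squares refit of the four Hill parameters from
the noisy titration points, used to verify the generated ground truth
is recoverable -- the plotting pipeline itself never fits, input files
already carry fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .model import ConfigurationError, ContractError, CurveFitParams, QHTSDataset, ResponseRecord
from .curves import hill_response, polarity
from .layout import ClassThresholds, assign_curve_class
from .formats_io import write_generic_qhts

_SMILES_MOTIFS = ("c1ccccc1", "C(=O)N", "CCO", "c1ccncc1", "C(F)(F)F", "S(=O)(=O)N")


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic screening campaign."""

    n_compounds: int = 100
    n_concs: int = 11
    conc_range: tuple[float, float] = (-9.0, -4.0)
    active_fraction: float = 0.3
    gain_fraction: float = 0.5
    readouts: tuple[str, ...] = ("FLuc", "NLuc")
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.active_fraction <= 1.0 and 0.0 <= self.gain_fraction <= 1.0):
            raise ConfigurationError("active_fraction and gain_fraction must lie in [0, 1]")
        if self.n_concs < 2:
            raise ConfigurationError("n_concs must be >= 2")
        if not self.conc_range[0] < self.conc_range[1]:
            raise ConfigurationError("conc_range must satisfy low < high")
        if self.n_compounds < 1:
            raise ConfigurationError("n_compounds must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not self.readouts:
            raise ConfigurationError("at least one readout name is required")


@dataclass
class LedgerEntry:
    """Ground truth for one generated record."""

    record_index: int
    compound: int
    comp_id: str
    readout: str
    active: bool
    params: Optional[CurveFitParams]
    polarity: Optional[str]
    curve_class: str


@dataclass
class Ledger:
    entries: list[LedgerEntry] = field(default_factory=list)

    @property
    def n_active_records(self) -> int:
        return sum(1 for e in self.entries if e.active)

    @property
    def n_gain_compounds(self) -> int:
        seen = {e.compound: e for e in self.entries}
        return sum(1 for e in seen.values() if e.polarity == "gain")

    @property
    def n_active_compounds(self) -> int:
        return len({e.compound for e in self.entries if e.active})


def generate_dataset(spec: GeneratorSpec) -> tuple[QHTSDataset, Ledger]:
    """Generate a schema-valid dataset plus its ground-truth ledger.

    One record per (compound, readout); active records have
    fit_output=1 and carry the true curve parameters, inactive records
    are points-only.  The same spec (same seed) yields an identical
    dataset.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.conc_range
    grid = np.linspace(lo, hi, spec.n_concs)

    n = spec.n_compounds
    active = rng.random(n) < spec.active_fraction
    gain = rng.random(n) < spec.gain_fraction
    log_ac50 = rng.uniform(lo + 0.5, hi - 0.5, n)
    hill = rng.uniform(0.5, 3.0, n)
    s0 = rng.uniform(-5.0, 5.0, n)
    eff_mag = rng.uniform(50.0, 100.0, n)

    thresholds = ClassThresholds()
    records: list[ResponseRecord] = []
    ledger = Ledger()
    for c in range(n):
        comp_id = f"CMP-{c:06d}"
        annotations = {
            "Compound_Name": f"compound-{c:06d}",
            "SMILES": _SMILES_MOTIFS[c % len(_SMILES_MOTIFS)] + "C" * (c % 4),
        }
        if active[c]:
            s_inf = s0[c] + (eff_mag[c] if gain[c] else -eff_mag[c])
            params = CurveFitParams(
                log_ac50_m=float(log_ac50[c]),
                s0=float(s0[c]),
                s_inf=float(s_inf),
                hill_slope=float(hill[c]),
            )
            clean = hill_response(grid, params)
        else:
            params = None
            clean = np.zeros(spec.n_concs)

        for readout in spec.readouts:
            noise = rng.normal(0.0, spec.noise_sd, spec.n_concs) if spec.noise_sd > 0 else 0.0
            responses = [float(v) for v in clean + noise]
            rec = ResponseRecord(
                fit_output=1 if active[c] else 0,
                comp_id=comp_id,
                readout=readout,
                responses=responses,
                params=params,
                annotations=dict(annotations),
            )
            ledger.entries.append(
                LedgerEntry(
                    record_index=len(records),
                    compound=c,
                    comp_id=comp_id,
                    readout=readout,
                    active=bool(active[c]),
                    params=params,
                    polarity=polarity(params) if params is not None else None,
                    curve_class=assign_curve_class(rec, list(grid), thresholds),
                )
            )
            records.append(rec)

    ds = QHTSDataset(
        format_tag="generic_qhts",
        log_conc_m=[float(v) for v in grid],
        records=records,
        source="synthetic",
    )
    return ds, ledger


def generate_example_file(path: str | Path, spec: Optional[GeneratorSpec] = None) -> QHTSDataset:
    """Write a ready-to-plot synthetic fixture (.csv or .xlsx) and return it."""
    ds, _ = generate_dataset(spec or GeneratorSpec())
    write_generic_qhts(ds, path)
    return ds


@dataclass
class FitResult:
    """Outcome of a Hill-curve refit; ``converged`` flags usable params."""

    params: Optional[CurveFitParams]
    converged: bool
    rmse: float = float("nan")


def _hill_f(x, log_ac50_m, s0, s_inf, hill_slope):
    expo = np.clip(hill_slope * (log_ac50_m - x), -300.0, 300.0)
    return s0 + (s_inf - s0) / (1.0 + np.power(10.0, expo))


def fit_hill(responses, grid) -> FitResult:
    """Least-squares four-parameter Hill fit of one titration series.

    Missing response cells are skipped; at least 5 observed points are
    required.  Non-convergence (or a degenerate flat series) returns a
    flagged result rather than raising, so calibration loops can skip
    the draw.
    """
    x = np.asarray(grid, dtype=float)
    y_raw = list(responses)
    mask = np.array([v is not None and np.isfinite(v) for v in y_raw])
    if mask.sum() < 5:
        raise ContractError("fit_hill needs at least 5 non-missing response points")
    x, y = x[mask], np.asarray([v for v, m in zip(y_raw, mask) if m], dtype=float)

    p0 = [float(x.mean()), float(y[0]), float(y[-1]), 1.0]
    lo_b = [x.min() - 3.0, -250.0, -250.0, 0.05]
    hi_b = [x.max() + 3.0, 250.0, 250.0, 10.0]
    try:
        popt, _ = curve_fit(
            _hill_f, x, y, p0=p0, bounds=(lo_b, hi_b), maxfev=20000,
            xtol=1e-13, ftol=1e-13, gtol=1e-13,
        )
    except (RuntimeError, ValueError):
        return FitResult(params=None, converged=False)
    params = CurveFitParams(*(float(v) for v in popt))
    resid = y - _hill_f(x, *popt)
    return FitResult(params=params, converged=True, rmse=float(np.sqrt(np.mean(resid**2))))
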