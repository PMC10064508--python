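"""Domain types shared across the package.

qHTS (quantitative high-throughput screening) tests every compound of a
library over a titration series, typically spanning 4-5 log units of
concentration.  Each record of a dataset is one (compound, readout) pair:
the normalized percent-activity responses over the shared concentration
grid, plus -- for records flagged for curve rendering -- the four
parameters of a fitted Hill concentration-response curve.

All concentrations are log10 of molar values; all responses are percent
activity relative to assay controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional


class QHTSError(Exception):
    """Base class for all errors raised by this package."""


class ContractError(QHTSError):
    """A function was called with arguments violating its preconditions."""


class FormatError(QHTSError):
    """The input file does not follow the generic_qhts layout."""


class UnsupportedDialectError(FormatError):
    """The file declares a dialect this package does not parse."""


class DataValidationError(QHTSError):
    """A record's content violates the schema (with a row/column locator)."""


class ConfigurationError(QHTSError):
    """User-supplied configuration (ordering keys, render format, ...) is invalid."""


PARAM_FIELDS = ("log_ac50_m", "s0", "s_inf", "hill_slope")


@dataclass(frozen=True)
class CurveFitParams:
    """Four-parameter Hill curve fit for one response record.

    Attributes
    ----------
    log_ac50_m
        log10 of the half-maximal concentration, in molar units.
    s0
        Response asymptote at zero concentration (% activity).
    s_inf
        Response asymptote at infinite concentration (% activity).
    hill_slope
        Hill coefficient; sign and magnitude set the direction and
        steepness of the sigmoid.  Must be nonzero to draw a curve.
    """

    log_ac50_m: float
    s0: float
    s_inf: float
    hill_slope: float

    def is_complete(self) -> bool:
        """True when all four parameters are present and finite."""
        return all(
            isinstance(getattr(self, f), (int, float)) and math.isfinite(getattr(self, f))
            for f in PARAM_FIELDS
        )

    def require_complete(self) -> None:
        for f in PARAM_FIELDS:
            v = getattr(self, f)
            if v is None or not math.isfinite(v):
                raise ContractError(f"curve parameter {f!r} is missing or non-finite")


def efficacy(params: Optional[CurveFitParams]) -> float:
    """Signed response span s_inf - s0 (% activity).

    Positive values are gain-of-signal responses, negative values
    loss-of-signal; zero is a flat (degenerate) curve.
    """
    if params is None:
        raise ContractError("curve parameters are absent; efficacy is undefined")
    params.require_complete()
    return params.s_inf - params.s0


@dataclass
class ResponseRecord:
    """One row of a qHTS dataset: a compound's responses for one readout.

    ``fit_output`` is the per-record rendering instruction from the input
    file: 1 draws the fitted curve plus points, 0 draws points only.
    ``comp_id`` values need not be unique -- a compound appears once per
    readout.  ``annotations`` carries any extra input columns (compound
    name, SMILES, ...) verbatim, in original column order.  ``responses``
    holds one value per grid concentration; ``None`` marks a masked or
    missing well and is skipped at plot time, never imputed.
    """

    fit_output: int
    comp_id: str
    readout: str
    responses: list[Optional[float]]
    params: Optional[CurveFitParams] = None
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fit_output not in (0, 1):
            raise DataValidationError(
                f"fit_output must be 0 or 1, got {self.fit_output!r}"
            )
        if not str(self.readout):
            raise DataValidationError("readout name must be non-empty")

    def has_complete_params(self) -> bool:
        return self.params is not None and self.params.is_complete()


@dataclass
class QHTSDataset:
    """An ordered qHTS dataset: shared concentration grid plus records.

    Record order is the input row order and is never changed by this
    type; ordering for display is a separate, explicit step.  The grid
    is global to the file (one header row); every record must carry
    exactly one response per grid point.
    """

    format_tag: str
    log_conc_m: list[float]
    records: list[ResponseRecord]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.log_conc_m) < 1:
            raise DataValidationError("concentration grid is empty")
        for i, c in enumerate(self.log_conc_m):
            if c is None or not math.isfinite(c):
                raise DataValidationError(
                    f"concentration grid value #{i} is missing or non-finite: {c!r}"
                )
        n = len(self.log_conc_m)
        for i, rec in enumerate(self.records):
            if len(rec.responses) != n:
                raise DataValidationError(
                    f"record {i} ({rec.comp_id!r}/{rec.readout!r}) has "
                    f"{len(rec.responses)} responses but the grid has {n} points"
                )

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_concs(self) -> int:
        return len(self.log_conc_m)


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    locator: str  # human-readable row/column reference
    message: str


@dataclass
class ValidationReport:
    """Outcome of schema validation; ``ok`` iff no error-severity issue."""

    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    def add(self, severity: str, locator: str, message: str) -> None:
        self.issues.append(Issue(severity, locator, message))

    def summary(self) -> str:
        lines = [f"{'OK' if self.ok else 'INVALID'}: "
                 f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        lines += [f"  [{i.severity}] {i.locator}: {i.message}" for i in self.issues]
        return "\n".join(lines)
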