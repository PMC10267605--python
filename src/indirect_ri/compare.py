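"""Run all three estimators and verify against a manufacturer range.

A laboratory verifying its in-use reference intervals compares each
indirect estimate with the manufacturer's IFU (instructions-for-use)
range.  Per limit, the relative deviation is 100*(method - IFU)/IFU; a
method is `comparable` when both deviations are within a threshold
(default 20%, configurable — the judgement is inherently a policy
choice) or when the IFU limit falls inside the method's bootstrap CI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .boxcox import ReferenceInterval
from .data_io import MeasurementSeries
from .errors import ConfigurationError, IndirectRIError, ReportError
from .hoffman import HoffmanConfig, fit_hoffman
from .kosmic import KosmicConfig, fit_kosmic
from .refiner import fit_refiner

__all__ = ["IFURange", "VerificationReport", "run_comparison"]

METHODS = ("hoffman", "kosmic", "refiner")
VERDICTS = ("comparable", "lower-discordant", "upper-discordant", "both-discordant")


@dataclass(frozen=True)
class IFURange:
    analyte: str
    lower: float
    upper: float
    source: str = "IFU"

    def __post_init__(self):
        if not 0 < self.lower < self.upper:
            raise ConfigurationError(
                f"IFU range needs 0 < lower < upper, got ({self.lower}, {self.upper})"
            )


@dataclass
class VerificationReport:
    analyte: str
    n: int
    ifu: IFURange
    threshold_pct: float
    intervals: Dict[str, Optional[ReferenceInterval]] = field(default_factory=dict)
    deviations: Dict[str, Optional[Tuple[float, float]]] = field(default_factory=dict)
    verdicts: Dict[str, Optional[str]] = field(default_factory=dict)
    errors: Dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in METHODS:
            ri = self.intervals.get(m)
            dev = self.deviations.get(m)
            rows.append(
                {
                    "analyte": self.analyte,
                    "n": self.n,
                    "method": m,
                    "ifu_lower": self.ifu.lower,
                    "ifu_upper": self.ifu.upper,
                    "ri_lower": ri.lower if ri else np.nan,
                    "ri_upper": ri.upper if ri else np.nan,
                    "dev_lower_pct": dev[0] if dev else np.nan,
                    "dev_upper_pct": dev[1] if dev else np.nan,
                    "verdict": self.verdicts.get(m) or "failed",
                    "error": self.errors.get(m, ""),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        doc = {
            "analyte": self.analyte,
            "n": self.n,
            "ifu": {"analyte": self.ifu.analyte, "lower": self.ifu.lower,
                    "upper": self.ifu.upper, "source": self.ifu.source},
            "threshold_pct": self.threshold_pct,
            "methods": {
                m: {
                    "ri": self.intervals[m].as_dict() if self.intervals.get(m) else None,
                    "deviation_pct": list(self.deviations[m]) if self.deviations.get(m) else None,
                    "verdict": self.verdicts.get(m),
                    "error": self.errors.get(m),
                }
                for m in METHODS
            },
        }
        if path is None:
            return doc
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
        return doc

    @classmethod
    def from_json(cls, path) -> "VerificationReport":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        rep = cls(
            analyte=doc["analyte"],
            n=doc["n"],
            ifu=IFURange(**doc["ifu"]),
            threshold_pct=doc["threshold_pct"],
        )
        for m, block in doc["methods"].items():
            if block.get("ri"):
                d = block["ri"]
                rep.intervals[m] = ReferenceInterval(
                    lower=d["lower"], upper=d["upper"], method=d["method"],
                    ci_lower=tuple(d["ci_lower"]) if d.get("ci_lower") else None,
                    ci_upper=tuple(d["ci_upper"]) if d.get("ci_upper") else None,
                    ci_level=d.get("ci_level"),
                )
            else:
                rep.intervals[m] = None
            rep.deviations[m] = tuple(block["deviation_pct"]) if block.get("deviation_pct") else None
            rep.verdicts[m] = block.get("verdict")
            if block.get("error"):
                rep.errors[m] = block["error"]
        return rep


def relative_deviation_pct(method_value: float, ifu_value: float) -> float:
    return 100.0 * (method_value - ifu_value) / ifu_value


def _limit_ok(dev_pct, ifu_value, ci, threshold) -> bool:
    if abs(dev_pct) <= threshold:
        return True
    return ci is not None and ci[0] <= ifu_value <= ci[1]


def _verdict(ri: ReferenceInterval, ifu: IFURange, threshold: float):
    dev = (
        relative_deviation_pct(ri.lower, ifu.lower),
        relative_deviation_pct(ri.upper, ifu.upper),
    )
    lo_ok = _limit_ok(dev[0], ifu.lower, ri.ci_lower, threshold)
    hi_ok = _limit_ok(dev[1], ifu.upper, ri.ci_upper, threshold)
    if lo_ok and hi_ok:
        v = "comparable"
    elif hi_ok:
        v = "lower-discordant"
    elif lo_ok:
        v = "upper-discordant"
    else:
        v = "both-discordant"
    return dev, v


def run_comparison(
    series: MeasurementSeries,
    ifu: IFURange,
    hoffman_config: Optional[HoffmanConfig] = None,
    kosmic_config: Optional[KosmicConfig] = None,
    refiner_levels: int = 3,
    refiner_boot: Optional[int] = None,
    seed: Optional[int] = None,
    threshold_pct: float = 20.0,
) -> VerificationReport:
    """Fit all three estimators and build the verification report.

    A single method's failure is recorded in the report without
    aborting the others; only all three failing raises
    :class:`ReportError`.
    """
    report = VerificationReport(
        analyte=series.analyte_name, n=series.n, ifu=ifu,
        threshold_pct=threshold_pct,
    )
    runners = {
        "hoffman": lambda: fit_hoffman(series, hoffman_config).ri,
        "kosmic": lambda: fit_kosmic(series, kosmic_config).ri,
        "refiner": lambda: fit_refiner(
            series, levels=refiner_levels, boot=refiner_boot, seed=seed
        ).ri,
    }
    for name, run in runners.items():
        try:
            ri = run()
        except IndirectRIError as exc:
            report.intervals[name] = None
            report.deviations[name] = None
            report.verdicts[name] = None
            report.errors[name] = f"{type(exc).__name__}: {exc}"
            continue
        dev, verdict = _verdict(ri, ifu, threshold_pct)
        report.intervals[name] = ri
        report.deviations[name] = dev
        report.verdicts[name] = verdict
    if len(report.errors) == len(runners):
        raise ReportError(f"all estimators failed: {report.errors}")
    return report
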