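"""CSV/JSON readers and writers, run configuration, and report formatting.

All interchange uses plain text: trace CSVs (``time_min,signal``) with a
JSON ground-truth sidecar, peak tables, spectrum CSVs (``mz,intensity``),
and a YAML run configuration. Report rounding follows the assay's reporting
conventions (RT to 3 dp, areas to integers, ratios to 3 dp, concentrations
to 3 significant figures) so reports can be diffed against bench records.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chromatogram import rsd
from .models import (
    CapsidModel,
    InstrumentSpec,
    Peak,
    QuantResult,
    SampleSpec,
    Spectrum,
    StandardCurve,
    Trace,
    VPDefinition,
)
from . import reference
from .synthetic import ChromatogramTruth

VP_ORDER = ("VP4", "VP1", "VP2", "VP0", "VP3")  # elution order

TRACE_COLUMNS = ["time_min", "signal"]
PEAK_COLUMNS = ["label", "rt_min", "area", "height", "fwhm_min", "start_min", "end_min"]
SPECTRUM_COLUMNS = ["mz", "intensity"]


# ---------------------------------------------------------------- traces

def write_trace(trace: Trace, path: str | Path) -> None:
    pd.DataFrame({"time_min": trace.time, "signal": trace.signal}).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_trace(path: str | Path, channel: str = "FLR") -> Trace:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV {path} missing columns: {sorted(missing)}")
    return Trace(
        time=df["time_min"].to_numpy(), signal=df["signal"].to_numpy(), channel=channel
    )


def write_ground_truth(truth: ChromatogramTruth, path: str | Path) -> None:
    payload = {
        "injected_capsids": truth.injected_capsids,
        "areas": truth.areas,
        "rts": truth.rts,
        "sample": asdict(truth.sample),
        "warnings": truth.warnings,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ------------------------------------------------------------ peak tables

def write_peak_table(peaks: list[Peak], path: str | Path) -> None:
    rows = [
        {
            "label": p.label or "",
            "rt_min": p.rt,
            "area": p.area,
            "height": p.height,
            "fwhm_min": p.fwhm,
            "start_min": p.start,
            "end_min": p.end,
        }
        for p in peaks
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, index=False, float_format="%.6g")


def read_peak_table(path: str | Path) -> list[Peak]:
    df = pd.read_csv(path)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path} missing columns: {sorted(missing)}")
    peaks = []
    for _, r in df.iterrows():
        label = r["label"]
        peaks.append(
            Peak(
                rt=float(r["rt_min"]),
                area=float(r["area"]),
                height=float(r["height"]),
                fwhm=float(r["fwhm_min"]),
                start=float(r["start_min"]),
                end=float(r["end_min"]),
                label=None if pd.isna(label) or label == "" else str(label),
            )
        )
    return peaks


# -------------------------------------------------------------- spectra

def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"mz": spec.mz, "intensity": spec.intensity}).to_csv(
        path, index=False, float_format="%.8g"
    )


def read_spectrum(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    missing = set(SPECTRUM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spectrum CSV {path} missing columns: {sorted(missing)}")
    return Spectrum(mz=df["mz"].to_numpy(), intensity=df["intensity"].to_numpy())


# ---------------------------------------------------------- configuration

@dataclass
class RunConfig:
    """Analysis/run configuration with method metadata.

    The gradient table, flow rate and column temperature are method
    metadata echoed into reports for provenance; nothing is computed from
    them. Analysis parameters (tolerances, thresholds, curve source)
    control the pipeline.
    """

    seed: int = 0
    sample: SampleSpec = field(
        default_factory=lambda: SampleSpec(capsid_conc=3.66e12, empty_fraction=0.343)
    )
    instrument: InstrumentSpec = field(default_factory=InstrumentSpec)
    capsid: CapsidModel = field(default_factory=CapsidModel)
    vps: dict[str, VPDefinition] = field(default_factory=reference.default_vps)
    injection_volume: float = 0.010  # mL
    dilution_factor: float = 1.0
    rt_tol: float = reference.DEFAULT_RT_TOL
    mass_tol: float = reference.DEFAULT_MASS_TOL
    min_prominence: float = 10.0
    process_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(reference.PROCESS_THRESHOLDS)
    )
    standard_curve: StandardCurve | None = None
    standard_points: list[tuple[float, float]] | None = None
    # Method metadata (stored, not computed on): two-stage gradient,
    # 0.4 mL/min, C4 1000 A column at 80 C.
    method_metadata: dict = field(
        default_factory=lambda: {
            "gradient_time_min_pctB": [[0.0, 25], [0.5, 25], [4.5, 42], [10.5, 48], [11.5, 80]],
            "flow_mL_min": 0.4,
            "column_temp_C": 80,
            "column": "C4 1000A 2.1x100mm 2.7um",
            "flr": {"ex_nm": 280, "em_nm": 352},
        }
    )

    def resolve_curve(self) -> StandardCurve:
        """Standard curve from coefficients or points, whichever is given."""
        from .quantify import fit_standard_curve

        if self.standard_curve is not None:
            return self.standard_curve
        if self.standard_points:
            return fit_standard_curve(self.standard_points)
        raise ValueError("config provides neither standard-curve coefficients nor points")


def _numeric(d: dict) -> dict:
    """Coerce scalar strings to float (YAML reads '1.0e12' as a string)."""
    out = {}
    for k, v in d.items():
        if isinstance(v, str):
            try:
                v = float(v)
            except ValueError:
                pass
        out[k] = v
    return out


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; absent keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()

    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "sample" in raw:
        cfg.sample = SampleSpec(**_numeric(raw["sample"]))
    if "instrument" in raw:
        cfg.instrument = InstrumentSpec(
            **{**asdict(cfg.instrument), **_numeric(raw["instrument"])}
        )
    if "capsid" in raw:
        c = raw["capsid"]
        cfg.capsid = CapsidModel(
            copies_per_capsid=c.get("copies_per_capsid", 60),
            empty_composition=tuple(c.get("empty_composition", ("VP0", "VP1", "VP3"))),
            full_composition=tuple(c.get("full_composition", ("VP1", "VP2", "VP3", "VP4"))),
        )
    if "vps" in raw:
        cfg.vps = {
            name: VPDefinition(
                name=name,
                calc_mass=v.get("calc_mass", reference.CALC_MASS[name]),
                trp_count=v.get("trp_count", reference.SYNTHETIC_TRP[name]),
                ref_rt=v.get("ref_rt", reference.REF_RT[name]),
                peak_sigma=v.get("peak_sigma", reference.DEFAULT_PEAK_SIGMA),
            )
            for name, v in raw["vps"].items()
        }
    for key in (
        "injection_volume",
        "dilution_factor",
        "rt_tol",
        "mass_tol",
        "min_prominence",
    ):
        if key in raw:
            setattr(cfg, key, float(raw[key]))
    if "process_thresholds" in raw:
        cfg.process_thresholds.update(raw["process_thresholds"])
    if "standard_curve" in raw:
        sc = _numeric(raw["standard_curve"])
        cfg.standard_curve = StandardCurve(
            slope=float(sc["slope"]),
            intercept=float(sc.get("intercept", 0.0)),
            r2=float(sc.get("r2", 1.0)),
            range=tuple(sc.get("range", reference.STANDARD_RANGE)),
        )
    if "standard_points" in raw:
        cfg.standard_points = [tuple(map(float, p)) for p in raw["standard_points"]]
    if "method_metadata" in raw:
        cfg.method_metadata.update(raw["method_metadata"])
    return cfg


# ---------------------------------------------------------------- reports

def _sigfig(x: float, n: int = 3) -> str:
    return f"{x:.{n - 1}E}"


def quant_results_frame(results: list[QuantResult], labels: list[str] | None = None) -> pd.DataFrame:
    """Tabulate per-injection quantification results in reporting layout."""
    labels = labels or [f"INJ-{i + 1}" for i in range(len(results))]
    rows = []
    for lab, r in zip(labels, results):
        row = {"injection": lab}
        for vp in VP_ORDER:
            row[vp] = round(r.per_vp_areas.get(vp, 0.0))
        row["total_area"] = round(sum(r.per_vp_areas.values()))
        row["vp2_plus_vp4"] = round(
            r.per_vp_areas.get("VP2", 0.0) + r.per_vp_areas.get("VP4", 0.0)
        )
        row["ef_ratio"] = round(r.ef_ratio, 3)
        row["capsid_conc"] = _sigfig(r.capsid_conc)
        row["extrapolated"] = r.extrapolated
        rows.append(row)
    return pd.DataFrame(rows)


def precision_report(results: list[QuantResult], labels: list[str] | None = None) -> str:
    """Human-readable precision block: per-injection rows, average, %RSD."""
    df = quant_results_frame(results, labels)
    lines = [df.to_string(index=False)]
    if len(results) >= 2:
        ratios = [r.ef_ratio for r in results]
        concs = [r.capsid_conc for r in results]
        totals = [sum(r.per_vp_areas.values()) for r in results]
        lines.append("")
        lines.append(
            f"Avg   total_area={np.mean(totals):,.0f}  ef_ratio={np.mean(ratios):.3f}  "
            f"capsid_conc={_sigfig(float(np.mean(concs)))}"
        )
        lines.append(
            f"%RSD  total_area={rsd(totals):.1f}  ef_ratio={rsd(ratios):.1f}  "
            f"capsid_conc={rsd(concs):.1f}"
        )
    return "\n".join(lines)


def accuracy_report(
    rows: list[tuple[str, float, float, float, float]]
) -> pd.DataFrame:
    """Spike-accuracy table: per mixture, theoretical vs measured.

    Each row is (name, theo_conc, theo_ratio, meas_conc, meas_ratio);
    recovery percentages are computed and rounded to integers.
    """
    from .quantify import accuracy_percent

    out = []
    for name, tc, tr, mc, mr in rows:
        out.append(
            {
                "mixture": name,
                "theoretical_conc": _sigfig(tc),
                "theoretical_ratio": round(tr, 4),
                "measured_conc": _sigfig(mc),
                "measured_ratio": round(mr, 4),
                "conc_accuracy_pct": int(accuracy_percent(mc, tc)),
                "ratio_accuracy_pct": int(accuracy_percent(mr, tr)),
            }
        )
    return pd.DataFrame(out)
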