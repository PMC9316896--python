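"""End-to-end cleaning-verification verdicts, pipeline, and I/O.

Verification of a hard-to-clean location is gated by visual inspection:
instrumental measurement happens only on a visually clean surface, so a
visual fail short-circuits everything (no statistics are computed).
Otherwise the location's n spot predictions are averaged; the mean is
checked against the residue acceptance limit (RAL) and against the
expected interval for an n-point mean from the margin-of-error model.

The module also provides the package's file formats (two-column text
spectra, a minimal JCAMP-DX dialect, delimited reports) and
``run_pipeline``, which chains simulate -> calibrate -> LOQ ->
sample-size -> verify into one reproducible bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import capability as cap
from . import chemometrics as chem
from . import loq as loqmod
from . import synthetic as syn

logger = logging.getLogger("rcvkit")

__all__ = [
    "VerificationConfig",
    "LocationMeasurements",
    "VerificationReport",
    "PipelineBundle",
    "SpectrumParseError",
    "verify_location",
    "run_pipeline",
    "load_config",
    "read_spectrum",
    "write_spectrum",
    "write_report",
    "report_frame",
]

REPORT_DECIMALS = 3  # ug/cm^2 values are reported at 3 decimals


class SpectrumParseError(ValueError):
    """Malformed spectrum file; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


# ---------------------------------------------------------------------------
# Verdicts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VerificationConfig:
    """Acceptance configuration for one verification campaign."""

    visual_limit: float = 0.6  # ug/cm^2
    ral: float = 1.0  # ug/cm^2, upper specification
    required_samples: int = 10
    moe: cap.MoeParameters = field(default_factory=cap.MoeParameters)
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.ral <= 0:
            raise ValueError("ral must be positive")
        if self.ral < self.visual_limit:
            raise ValueError("ral below the visual limit is not a valid configuration")
        if self.required_samples < 2:
            raise ValueError("required_samples must be >= 2")


@dataclass(frozen=True)
class LocationMeasurements:
    """Spot predictions collected at one hard-to-clean location."""

    label: str
    visual_pass: bool
    values: tuple[float, ...] = ()
    below_loq_flags: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        flags = tuple(self.below_loq_flags) or tuple(False for _ in vals)
        if len(flags) != len(vals):
            raise ValueError("below_loq_flags length must match values")
        object.__setattr__(self, "below_loq_flags", flags)


@dataclass(frozen=True)
class VerificationReport:
    """Outcome for one location.

    ``verdict`` is one of pass / fail / not-evaluated-visual-fail /
    inconclusive.  Statistical fields are None whenever the visual gate
    fails or the measurement count is wrong.
    """

    label: str
    verdict: str
    mean: float | None = None
    interval: tuple[float, float] | None = None
    within_interval: bool | None = None
    ral_compliant: bool | None = None
    n_measurements: int = 0
    n_below_loq: int = 0
    reason: str = ""
    config: VerificationConfig | None = None


def verify_location(
    meas: LocationMeasurements, cfg: VerificationConfig | None = None
) -> VerificationReport:
    """Verdict for one location under the visual gate and the RAL.

    A visual fail returns immediately with no statistics.  A wrong
    measurement count yields an inconclusive verdict (with reason)
    rather than an exception.  Otherwise the mean of the predictions is
    compared with the RAL (pass/fail) and with the expected interval
    for a mean of ``required_samples`` points.
    """
    cfg = cfg or VerificationConfig()
    if not meas.visual_pass:
        return VerificationReport(
            label=meas.label,
            verdict="not-evaluated-visual-fail",
            reason="visual inspection failed; cleaning must be repeated",
            config=cfg,
        )
    n = len(meas.values)
    if n != cfg.required_samples:
        return VerificationReport(
            label=meas.label,
            verdict="inconclusive",
            n_measurements=n,
            reason=f"expected {cfg.required_samples} measurements, got {n}",
            config=cfg,
        )
    mean = float(np.mean(meas.values))
    interval = cap.mean_interval(cfg.moe, cfg.required_samples)
    within = interval.contains(mean)
    ral_ok = mean <= cfg.ral
    return VerificationReport(
        label=meas.label,
        verdict="pass" if ral_ok else "fail",
        mean=mean,
        interval=(interval.lower, interval.upper),
        within_interval=within,
        ral_compliant=ral_ok,
        n_measurements=n,
        n_below_loq=sum(meas.below_loq_flags),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Spectrum I/O
# ---------------------------------------------------------------------------


def write_spectrum(spectrum: syn.Spectrum, path, dialect: str = "two-column-text") -> None:
    """Write a spectrum; the text dialect round-trips bit-exactly."""
    path = Path(path)
    if dialect == "two-column-text":
        lines = [
            "# rcvkit spectrum",
            "# columns: wavenumber_cm-1 absorbance",
            f"# n_scans_averaged: {spectrum.n_scans_averaged}",
        ]
        lines += [
            f"{float(wn)!r} {float(ab)!r}"
            for wn, ab in zip(spectrum.wavenumbers, spectrum.absorbance)
        ]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "jcamp-dx":
        _write_jcamp(spectrum, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_spectrum(path, dialect: str = "two-column-text") -> syn.Spectrum:
    """Read a spectrum, re-sorting (with a warning) if stored descending."""
    path = Path(path)
    if dialect == "jcamp-dx":
        return _read_jcamp(path)
    if dialect != "two-column-text":
        raise ValueError(f"unknown dialect {dialect!r}")
    wn, ab = [], []
    n_scans = 1
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if "n_scans_averaged:" in stripped:
                try:
                    n_scans = int(stripped.split(":", 1)[1])
                except ValueError:
                    raise SpectrumParseError(path, line_no, "bad n_scans_averaged header")
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise SpectrumParseError(path, line_no, f"expected 2 columns, got {len(parts)}")
        try:
            wn.append(float(parts[0]))
            ab.append(float(parts[1]))
        except ValueError:
            raise SpectrumParseError(path, line_no, f"non-numeric value in {stripped!r}")
    if not wn:
        raise SpectrumParseError(path, 0, "no data lines")
    wn_arr, ab_arr = np.array(wn), np.array(ab)
    if len(wn_arr) > 1 and not (np.diff(wn_arr) > 0).all():
        logger.warning("[io] %s: wavenumbers not ascending; re-sorting", path)
        order = np.argsort(wn_arr)
        wn_arr, ab_arr = wn_arr[order], ab_arr[order]
    return syn.Spectrum(wavenumbers=wn_arr, absorbance=ab_arr, n_scans_averaged=n_scans)


_JCAMP_YFACTOR = 1e-8  # fixed-point quantum for absorbance


def _write_jcamp(spectrum: syn.Spectrum, path: Path) -> None:
    """Minimal JCAMP-DX writer: ##XYDATA=(X++(Y..Y)), AFFN, fixed point."""
    wn = spectrum.wavenumbers
    y_int = np.round(spectrum.absorbance / _JCAMP_YFACTOR).astype(np.int64)
    step = (wn[-1] - wn[0]) / (len(wn) - 1) if len(wn) > 1 else 1.0
    lines = [
        "##TITLE=rcvkit spectrum",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##FIRSTX={float(wn[0])!r}",
        f"##LASTX={float(wn[-1])!r}",
        f"##DELTAX={float(step)!r}",
        "##XFACTOR=1",
        f"##YFACTOR={_JCAMP_YFACTOR!r}",
        f"##NPOINTS={len(wn)}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, len(wn), per_line):
        ys = " ".join(str(v) for v in y_int[i : i + per_line])
        lines.append(f"{float(wn[i])!r} {ys}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def _read_jcamp(path: Path) -> syn.Spectrum:
    yfactor = 1.0
    npoints = None
    in_data = False
    xs: list[float] = []
    ys: list[float] = []
    deltax = None
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("##"):
            key, _, val = s[2:].partition("=")
            key = key.strip().upper()
            if key == "YFACTOR":
                yfactor = float(val)
            elif key == "NPOINTS":
                npoints = int(val)
            elif key == "DELTAX":
                deltax = float(val)
            elif key == "XYDATA":
                in_data = True
            elif key == "END":
                in_data = False
            continue
        if in_data:
            parts = s.split()
            try:
                x0 = float(parts[0])
                yline = [float(p) * yfactor for p in parts[1:]]
            except (ValueError, IndexError):
                raise SpectrumParseError(path, line_no, "bad XYDATA line")
            if deltax is None:
                raise SpectrumParseError(path, line_no, "XYDATA before DELTAX")
            xs.extend(x0 + deltax * np.arange(len(yline)))
            ys.extend(yline)
    if not xs:
        raise SpectrumParseError(path, 0, "no XYDATA found")
    if npoints is not None and npoints != len(xs):
        raise SpectrumParseError(path, 0, f"NPOINTS={npoints} but read {len(xs)} points")
    wn_arr, ab_arr = np.array(xs), np.array(ys)
    if len(wn_arr) > 1 and not (np.diff(wn_arr) > 0).all():
        logger.warning("[io] %s: wavenumbers not ascending; re-sorting", path)
        order = np.argsort(wn_arr)
        wn_arr, ab_arr = wn_arr[order], ab_arr[order]
    return syn.Spectrum(wavenumbers=wn_arr, absorbance=ab_arr)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def report_frame(reports: Sequence[VerificationReport]) -> pd.DataFrame:
    """Tabular view of verification reports, 3-decimal densities."""
    rows = []
    for r in reports:
        rows.append(
            {
                "location": r.label,
                "verdict": r.verdict,
                "mean": None if r.mean is None else round(r.mean, REPORT_DECIMALS),
                "interval_lower": None if r.interval is None else round(r.interval[0], REPORT_DECIMALS),
                "interval_upper": None if r.interval is None else round(r.interval[1], REPORT_DECIMALS),
                "within_interval": r.within_interval,
                "ral_compliant": r.ral_compliant,
                "n_measurements": r.n_measurements,
                "n_below_loq": r.n_below_loq,
                "reason": r.reason,
            }
        )
    columns = [
        "location", "verdict", "mean", "interval_lower", "interval_upper",
        "within_interval", "ral_compliant", "n_measurements", "n_below_loq", "reason",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_report(
    reports: Sequence[VerificationReport], path, format: str = "delimited-table"
) -> None:
    """Serialize reports deterministically (same input -> same bytes)."""
    path = Path(path)
    frame = report_frame(reports)
    if format == "delimited-table":
        path.write_text(frame.to_csv(index=False, float_format=f"%.{REPORT_DECIMALS}f"))
    elif format == "human-readable-text":
        lines = ["Cleaning verification report", "=" * 28]
        for r in reports:
            lines.append(f"Location: {r.label}")
            lines.append(f"  verdict: {r.verdict}")
            if r.mean is not None:
                lines.append(f"  mean surface residue: {r.mean:.3f} ug/cm^2")
                lines.append(
                    f"  expected interval: {r.interval[0]:.3f}-{r.interval[1]:.3f} ug/cm^2"
                    f" (within: {'yes' if r.within_interval else 'no'})"
                )
                lines.append(f"  RAL compliant: {'yes' if r.ral_compliant else 'no'}")
            if r.reason:
                lines.append(f"  note: {r.reason}")
            lines.append("")
        path.write_text("\n".join(lines))
    else:
        raise ValueError(f"unknown report format {format!r}")


# ---------------------------------------------------------------------------
# Configuration and pipeline
# ---------------------------------------------------------------------------

PIPELINE_DEFAULTS: dict = {
    # acceptance configuration
    "visual_limit": 0.6,
    "ral": 1.0,
    "required_samples": 10,
    "mean": 0.6,
    "sd": 0.3,
    "confidence": 0.9973,
    # capability
    "n_max": 30,
    "target_cpk": 1.67,
    # calibration design
    "levels": [0.6, 1.2, 1.8, 2.4, 3.0],
    "replicates": 5,
    "max_components": 3,
    "cv_folds": 3,
    # LOQ study
    "loq_density": 0.3,
    "loq_replicates": 10,
    # coupons
    "n_coupons": 3,
    "coupon_width": 25.0,
    "coupon_height": 25.0,
    "inhomogeneity": 0.1,
    "solution_concentration": 2.0e-4,
    # instrument
    "wavenumber_min": 650.0,
    "wavenumber_max": 4000.0,
    "grid_step": 2.0,
    "spot_area": 1.76,
    "scans_per_spectrum": 16,
    "noise_sd_per_scan": 0.004,
    "baseline_shift_sd": 0.01,
    # model windows
    "windows": [[1200.20, 1259.84]],
}


def load_config(path) -> dict:
    """Flat key-value YAML config, merged over the pipeline defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ValueError("config must be a flat key-value mapping")
    unknown = set(raw) - set(PIPELINE_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = dict(PIPELINE_DEFAULTS)
    merged.update(raw)
    return merged


def _instrument_from(cfg: Mapping) -> syn.InstrumentProfile:
    return syn.InstrumentProfile(
        wavenumber_min=cfg["wavenumber_min"],
        wavenumber_max=cfg["wavenumber_max"],
        grid_step=cfg["grid_step"],
        spot_area=cfg["spot_area"],
        scans_per_spectrum=cfg["scans_per_spectrum"],
        noise_sd_per_scan=cfg["noise_sd_per_scan"],
        baseline_shift_sd=cfg["baseline_shift_sd"],
    )


def _deposition_from(cfg: Mapping) -> syn.DepositionProfile:
    return syn.DepositionProfile(
        coupon_width=cfg["coupon_width"],
        coupon_height=cfg["coupon_height"],
        solution_concentration=cfg["solution_concentration"],
        inhomogeneity=cfg["inhomogeneity"],
    )


@dataclass(frozen=True)
class PipelineBundle:
    """Everything one pipeline run produced, with provenance."""

    config: dict
    seed: int
    capability_table: pd.DataFrame
    min_samples: int | None
    capability_note: str
    loq_result: loqmod.LoqResult
    model: chem.PlsModel
    n_components: int
    reports: tuple[VerificationReport, ...]
    spot_rsd_percent: tuple[float, ...]


def run_pipeline(
    config: Mapping | str | Path | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> PipelineBundle:
    """Simulate -> calibrate -> LOQ -> sample size -> verify.

    ``config`` may be a mapping, a YAML path, or None for defaults.
    Reruns with the same seed and config produce identical bundles; when
    ``out_dir`` is given every artifact is written there with
    provenance.
    """
    if config is None:
        cfg = dict(PIPELINE_DEFAULTS)
    elif isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = dict(PIPELINE_DEFAULTS)
        unknown = set(config) - set(PIPELINE_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    if cfg["ral"] < cfg["visual_limit"]:
        raise ValueError("ral below the visual limit is not a valid configuration")

    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    instrument = _instrument_from(cfg)
    deposition = _deposition_from(cfg)
    signature = syn.default_signature()
    moe = cap.MoeParameters(
        mean=cfg["mean"], sd=cfg["sd"], confidence=cfg["confidence"], ral=cfg["ral"]
    )
    vcfg = VerificationConfig(
        visual_limit=cfg["visual_limit"],
        ral=cfg["ral"],
        required_samples=cfg["required_samples"],
        moe=moe,
        model_id=f"pls-seed{seed}",
    )

    logger.info("[calibrate] fitting PLS on %d levels x %d replicates",
                len(cfg["levels"]), cfg["replicates"])
    windows = chem.SpectralWindowSet(tuple(tuple(w) for w in cfg["windows"]))
    spec = chem.PreprocessSpec(windows=windows)
    cal_spectra = syn.generate_calibration_set(
        cfg["levels"], cfg["replicates"], signature, instrument, seed=int(seeds[0])
    )
    cal = chem.build_calibration_set(cal_spectra, spec=spec)
    n_comp = chem.choose_components_cv(cal, cfg["max_components"], cfg["cv_folds"])
    model = chem.fit_pls(cal, n_comp)

    logger.info("[loq] %d pseudo-blank replicates at %.3g ug/cm^2",
                cfg["loq_replicates"], cfg["loq_density"])
    blanks = syn.generate_pseudo_blank_replicates(
        cfg["loq_density"], cfg["loq_replicates"], signature, instrument, seed=int(seeds[1])
    )
    blank_preds = [chem.predict(model, s).value for s in blanks]
    loq_result = loqmod.loq_from_replicates(
        loqmod.ReplicateSet(np.array(blank_preds), source_note="fixed point, shared baseline")
    )
    model = loqmod.apply_calibration_floor(model, loq_result)

    logger.info("[sample-size] capability curve to n=%d", cfg["n_max"])
    curve = cap.capability_curve(moe, cfg["n_max"])
    min_n = cap.min_samples_for_cpk(cfg["target_cpk"], moe)
    note = cap.discrepancy_note(moe)

    logger.info("[verify] %d coupons, %d spots each", cfg["n_coupons"], cfg["required_samples"])
    reports = []
    rsds = []
    rng = np.random.default_rng(int(seeds[2]))
    for i in range(cfg["n_coupons"]):
        surface = syn.generate_coupon(
            cfg["visual_limit"], deposition, seed=int(rng.integers(2**31))
        )
        densities = syn.sample_random_spots(
            surface, cfg["required_samples"], instrument.spot_area,
            seed=int(rng.integers(2**31)),
        )
        preds = [
            chem.predict(
                model,
                syn.simulate_measurement(
                    d, signature, instrument, seed=int(rng.integers(2**31))
                ),
            )
            for d in densities
        ]
        values = [p.value for p in preds]
        rsds.append(cap.percent_rsd(values) if np.mean(values) > 0 else float("nan"))
        meas = LocationMeasurements(
            label=f"coupon-{i + 1}",
            visual_pass=surface.mean_density >= cfg["visual_limit"] * 0.999,
            values=tuple(values),
            below_loq_flags=tuple(p.below_floor for p in preds),
        )
        reports.append(verify_location(meas, vcfg))

    bundle = PipelineBundle(
        config=cfg,
        seed=seed,
        capability_table=curve,
        min_samples=min_n,
        capability_note=note,
        loq_result=loq_result,
        model=model,
        n_components=n_comp,
        reports=tuple(reports),
        spot_rsd_percent=tuple(rsds),
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: PipelineBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.capability_table.to_csv(out_dir / "capability.csv", index=False)
    (out_dir / "capability_note.txt").write_text(bundle.capability_note + "\n")
    (out_dir / "model.json").write_text(chem.model_to_json(bundle.model))
    (out_dir / "loq.json").write_text(
        json.dumps(dataclasses.asdict(bundle.loq_result), indent=1) + "\n"
    )
    write_report(bundle.reports, out_dir / "verification.csv")
    write_report(bundle.reports, out_dir / "verification.txt", "human-readable-text")
    provenance = {
        "seed": bundle.seed,
        "config": bundle.config,
        "n_components": bundle.n_components,
        "min_samples_for_target_cpk": bundle.min_samples,
        "spot_rsd_percent": list(bundle.spot_rsd_percent),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True) + "\n")
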