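"""File formats, run configuration and the pipeline driver.

Transients travel as plain-text delimited tables (comma or tab) with a
commented header carrying the record metadata; every output table carries
units in its header and every run directory contains the exact
configuration used plus a manifest with file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .estimators import estimate_step_response, fit_fluidity_vs_SL, fit_relation
from .mech_model import ForceStepProtocol, TitinMechParams, Transient
from .synthetic import SyntheticStudyConfig, gen_mech_dataset, gen_xray_observations
from .xray import FilamentAxialModel, scan_extension_onset

__all__ = [
    "ParseError",
    "RunConfig",
    "read_transient",
    "write_transient",
    "load_config",
    "save_config",
    "run_pipeline",
]

log = logging.getLogger("titinmech")

HEADER_MAGIC = "titin-transient v1"


class ParseError(ValueError):
    """Malformed transient file."""


def write_transient(transient: Transient, path: str | Path) -> None:
    """Write a transient as a comma-delimited text table with metadata header."""
    path = Path(path)
    lines = [f"# {HEADER_MAGIC}"]
    lines.append(f"# SL0_um = {transient.SL0!r}")
    lines.append(f"# state = {transient.state}")
    for key in ("fiber", "seed", "provenance"):
        if key in transient.meta:
            lines.append(f"# {key} = {transient.meta[key]}")
    lines.append("time_s,force_pN,x_nm")
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, np.column_stack([transient.time, transient.force, transient.x]),
                   fmt="%.17g", delimiter=",")


def read_transient(path: str | Path) -> Transient:
    """Read a transient written by :func:`write_transient`.

    Comma- and tab-delimited variants are both accepted.  Raises
    :class:`ParseError` naming the offending line for malformed headers or
    non-monotone time.
    """
    path = Path(path)
    meta: dict = {}
    SL0: Optional[float] = None
    state: Optional[str] = None
    data_lines: list[tuple[int, str]] = []
    delimiter = ","
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    key, value = key.strip(), value.strip()
                    if key == "SL0_um":
                        try:
                            SL0 = float(value)
                        except ValueError as exc:
                            raise ParseError(
                                f"{path}:{lineno}: bad SL0_um value {value!r}"
                            ) from exc
                    elif key == "state":
                        state = value
                    else:
                        meta[key] = value
                continue
            if line[0].isalpha():  # column header row
                delimiter = "\t" if "\t" in line else ","
                continue
            data_lines.append((lineno, line))
    if SL0 is None or state is None:
        raise ParseError(f"{path}:1: missing SL0_um/state in header")
    if not data_lines:
        raise ParseError(f"{path}: no data rows")
    rows = []
    for lineno, line in data_lines:
        sep = "\t" if "\t" in line else delimiter
        parts = [p for p in line.replace(sep, ",").split(",") if p != ""]
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
    arr = np.asarray(rows)
    time = arr[:, 0]
    bad = np.nonzero(np.diff(time) <= 0)[0]
    if len(bad):
        raise ParseError(
            f"{path}:{data_lines[int(bad[0]) + 1][0]}: time not strictly increasing"
        )
    return Transient(time=time, force=arr[:, 1], x=arr[:, 2], SL0=SL0, state=state,
                     meta=meta)


# --- run configuration ------------------------------------------------------


class MechParamsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    e1: float = 7.30
    e2: float = 3.02
    tau2: float = 0.5e-3
    eta3: float = 6.25
    eta_sh: float = 1.60e-3
    fluidity_max: float = 1e3 * (3.15 - 2.2) / (3.15 - 2.7)
    SL_ref: float = 2.2
    SL_c: float = 3.15
    e_pevk: float = 1.0 / 0.65

    def to_params(self) -> TitinMechParams:
        return TitinMechParams(**self.model_dump())


class ProtocolBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    delta_T: float = 50.0
    baseline_force: float = 0.0
    rise_time: float = 150e-6
    t_step: float = 5e-3
    duration: float = 0.25
    dt: float = 1e-5

    def to_protocol(self) -> ForceStepProtocol:
        return ForceStepProtocol(**self.model_dump())


class XrayBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_crowns: int = 49
    d: float = 14.3
    d_ext: float = 14.4
    onset_layer: Optional[int] = None
    HBZ: float = 80.0
    triplet_delta: float = 0.0
    true_onset: int = 3
    onset_grid_max: int = 10

    def to_model(self) -> FilamentAxialModel:
        return FilamentAxialModel(
            n_crowns=self.n_crowns, d=self.d, d_ext=self.d_ext,
            onset_layer=self.onset_layer, HBZ=self.HBZ,
            triplet_delta=self.triplet_delta,
        )


class SyntheticBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    SL_list: list[float] = Field(default_factory=lambda: [2.5, 2.7, 3.0])
    delta_T_list: list[float] = Field(default_factory=lambda: [9.0, 20.0, 25.0, 50.0])
    n_fibers: int = 4
    trace_noise_sd: float = 0.5
    force_noise_sd: float = 0.5
    xray_noise_rel: float = 0.02
    param_jitter_cv: float = 0.05


class RunConfig(BaseModel):
    """Top-level run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    log_level: str = "INFO"
    mech_params: dict[str, MechParamsBlock] = Field(default_factory=dict)
    protocol: ProtocolBlock = Field(default_factory=ProtocolBlock)
    xray: XrayBlock = Field(default_factory=XrayBlock)
    synthetic: SyntheticBlock = Field(default_factory=SyntheticBlock)


def load_config(path: str | Path) -> RunConfig:
    with Path(path).open() as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)


def save_config(config: RunConfig, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)


# --- pipeline ---------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _study_config(config: RunConfig) -> SyntheticStudyConfig:
    kwargs = dict(
        seed=config.seed,
        SL_list=tuple(config.synthetic.SL_list),
        delta_T_list=tuple(config.synthetic.delta_T_list),
        n_fibers=config.synthetic.n_fibers,
        trace_noise_sd=config.synthetic.trace_noise_sd,
        force_noise_sd=config.synthetic.force_noise_sd,
        xray_noise_rel=config.synthetic.xray_noise_rel,
        param_jitter_cv=config.synthetic.param_jitter_cv,
        protocol=config.protocol.to_protocol(),
    )
    if config.mech_params:
        kwargs["params_per_SL"] = tuple(
            sorted((float(sl), block.to_params()) for sl, block in config.mech_params.items())
        )
    return SyntheticStudyConfig(**kwargs)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate data, estimate, fit relations and scan the extension onset.

    Writes the transients, a per-record estimate table, per-SL linear-fit
    summaries (a Table-1-shaped recovery of the injected parameters), the
    fluidity-vs-SL fit, the onset-scan residual curve and a manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    study = _study_config(config)

    log.info("stage=gen-data seed=%d fibers=%d", study.seed, study.n_fibers)
    transients = gen_mech_dataset(study)
    traces_dir = out / "transients"
    traces_dir.mkdir(exist_ok=True)
    paths = []
    for i, tr in enumerate(transients):
        p = traces_dir / f"transient_{i:04d}.csv"
        write_transient(tr, p)
        paths.append(p)

    log.info("stage=estimate n_records=%d", len(transients))
    rows = []
    for tr in transients:
        protocol = tr.meta.get(
            "protocol",
            replace(study.protocol, delta_T=float(tr.force[-1] - tr.force[0])),
        )
        est = estimate_step_response(tr, protocol)
        rows.append(
            dict(fiber=tr.meta.get("fiber", "?"), SL0_um=tr.SL0, state=tr.state,
                 delta_T_pN=est.delta_T, L1_nm=est.L1, L2_nm=est.L2,
                 Vi_nm_per_s=est.Vi, V3_nm_per_s=est.V3, Vsh_nm_per_s=est.Vsh)
        )
    est_df = pd.DataFrame(rows)
    est_path = out / "estimates.csv"
    est_df.to_csv(est_path, index=False)

    log.info("stage=fit-relations")
    summary = []
    for SL in sorted(est_df["SL0_um"].unique()):
        sub = est_df[(est_df.SL0_um == SL) & (est_df.state == "ON")
                     & (est_df.delta_T_pN > 0)]
        if len(sub) >= 2:
            l2_fit = fit_relation(list(zip(sub.delta_T_pN, sub.L2_nm)))
            l1_fit = fit_relation(list(zip(sub.delta_T_pN, sub.L1_nm)))
            v3_fit = fit_relation(list(zip(sub.delta_T_pN, sub.V3_nm_per_s)))
            summary.append(
                dict(SL_um=SL, e1_pN_per_nm=1.0 / l1_fit.slope,
                     e2_pN_per_nm=1.0 / l2_fit.slope,
                     eta3_pN_s_per_nm=1.0 / v3_fit.slope)
            )
    summary_df = pd.DataFrame(summary)
    summary_path = out / "table1_recovery.csv"
    summary_df.to_csv(summary_path, index=False)

    fluidities = []
    for SL in sorted(est_df["SL0_um"].unique()):
        sub = est_df[(est_df.SL0_um == SL) & (est_df.state == "OFF")]
        if len(sub) >= 2:
            vi_fit = fit_relation(list(zip(sub.delta_T_pN, sub.Vi_nm_per_s)))
            fluidities.append((float(SL), vi_fit.slope))
    fluidity_path = out / "fluidity_fit.csv"
    if len(fluidities) >= 2:
        flu_fit = fit_fluidity_vs_SL(fluidities)
        pd.DataFrame(
            [dict(slope_nm_per_s_pN_um=flu_fit.slope,
                  intercept_nm_per_s_pN=flu_fit.intercept,
                  SL_c_um=flu_fit.abscissa_intercept,
                  SL_c_se_um=flu_fit.abscissa_intercept_se)]
        ).to_csv(fluidity_path, index=False)

    log.info("stage=scan-onset true_onset=%d", config.xray.true_onset)
    observations = gen_xray_observations(study, config.xray.true_onset,
                                         template=config.xray.to_model())
    scan = scan_extension_onset(observations, config.xray.to_model(),
                                range(1, config.xray.onset_grid_max + 1))
    scan_path = out / "onset_scan.csv"
    pd.DataFrame({"onset_layer": scan.onsets, "rss": scan.rss}).to_csv(
        scan_path, index=False
    )

    config_path = out / "config.yaml"
    save_config(config, config_path)
    manifest = {
        "seed": config.seed,
        "n_transients": len(paths),
        "best_onset": scan.best_onset,
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in [est_path, summary_path, scan_path, config_path]
            + ([fluidity_path] if fluidity_path.exists() else [])
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("stage=done out=%s", out)
    return out
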