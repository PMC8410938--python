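"""Session-level orchestration: manifests, pipeline, outputs, provenance.

A session manifest (YAML) lists the per-trial donor/acceptor/behaviour TIFF
stacks together with stimulus metadata and per-window alignment (bregma
pixel, midline angle).  ``run_pipeline`` executes the fixed stage order —
movement classification, then for quiet trials preprocessing, vessel
masking/atlas registration, region traces, response metrics (or paired-pulse
adaptation), and trial-averaged maps — and writes tidy CSVs, float TIFF
maps, and a machine-readable provenance record.  Every numeric output column
is documented in a generated data dictionary.

All thresholds and windows live in :class:`PipelineConfig` (YAML-serialisable)
with the protocol's values as defaults; nothing is hard-coded in the stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .maps import VoltageMap, average_aligned_maps, render_map_frames, trial_map
from .metrics import compute_metrics, paired_pulse
from .movement import calibrate_noise, changed_pixel_fraction, classify_trial
from .preprocessing import DualChannelSequence, PreprocessConfig, bin_spatial, preprocess
from .registration import AtlasLayout, default_layout, make_vessel_mask, rasterize_atlas, region_trace

__all__ = [
    "SessionError",
    "ManifestSchemaError",
    "MissingFileError",
    "FrameCountError",
    "DtypeError",
    "TrialSpec",
    "SessionManifest",
    "PipelineConfig",
    "load_session",
    "read_stack",
    "run_pipeline",
    "write_outputs",
    "validate_provenance",
]


class SessionError(Exception):
    """Base class for session loading/validation errors."""

    code = "session-error"


class ManifestSchemaError(SessionError):
    code = "schema"


class MissingFileError(SessionError):
    code = "missing-file"


class FrameCountError(SessionError):
    code = "frame-count"


class DtypeError(SessionError):
    code = "dtype"


PAIRED_TYPES = {"paw_pair", "paw_then_whisker", "whisker_then_paw"}
CONDITIONS = {"control", "scopolamine", "ach_lesion", "lesion_control"}


@dataclass
class TrialSpec:
    trial_id: str
    stimulus_type: str
    stim_frames: tuple[int, ...]
    donor: Path
    acceptor: Path
    behavior: Path
    bregma_px: tuple[float, float]
    midline_angle_deg: float = 0.0
    interstim_ms: float | None = None


@dataclass
class SessionManifest:
    session_id: str
    mouse_id: str
    condition: str
    frame_rate: float
    n_frames: int
    dark_frames: tuple[int, int]
    pixel_size_um_binned: float
    bin_factor: int
    trials: list[TrialSpec]
    calibration_behavior: Path | None = None
    root: Path = Path(".")


def _require(doc: dict, key: str, where: str):
    if key not in doc:
        raise ManifestSchemaError(f"{where}: missing required field {key!r}")
    return doc[key]


def load_session(manifest_path: str | Path) -> SessionManifest:
    """Parse and validate a session manifest; stacks stay on disk (lazy).

    Schema violations report the offending field path; each referenced file
    must resolve relative to the manifest directory at load time.
    """
    path = Path(manifest_path)
    if not path.exists():
        raise MissingFileError(f"manifest not found: {path}")
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ManifestSchemaError("manifest root must be a mapping")
    root = path.parent
    # top-level schema first, so field errors surface before file checks
    for key in (
        "session_id",
        "mouse_id",
        "frame_rate",
        "n_frames",
        "dark_frames",
        "pixel_size_um_binned",
        "bin_factor",
    ):
        _require(doc, key, "manifest")
    condition = _require(doc, "condition", "manifest")
    if condition not in CONDITIONS:
        raise ManifestSchemaError(
            f"manifest.condition: {condition!r} not one of {sorted(CONDITIONS)}"
        )
    trials_doc = _require(doc, "trials", "manifest")
    if not trials_doc:
        raise ManifestSchemaError("manifest.trials: at least one trial required")
    trials: list[TrialSpec] = []
    seen_ids: set[str] = set()
    for i, t in enumerate(trials_doc):
        where = f"manifest.trials[{i}]"
        tid = str(_require(t, "trial_id", where))
        if tid in seen_ids:
            raise ManifestSchemaError(f"{where}.trial_id: duplicate id {tid!r}")
        seen_ids.add(tid)
        stype = _require(t, "stimulus_type", where)
        stim_frames = tuple(int(s) for s in _require(t, "stim_frames", where))
        interstim = t.get("interstim_ms")
        if (stype in PAIRED_TYPES) != (interstim is not None):
            raise ManifestSchemaError(
                f"{where}.interstim_ms must be present iff stimulus type is paired"
            )
        paths = {}
        for key in ("donor", "acceptor", "behavior"):
            p = root / _require(t, key, where)
            if not p.exists():
                raise MissingFileError(f"{where}.{key}: file not found for trial {tid!r}: {p}")
            paths[key] = p
        trials.append(
            TrialSpec(
                trial_id=tid,
                stimulus_type=stype,
                stim_frames=stim_frames,
                donor=paths["donor"],
                acceptor=paths["acceptor"],
                behavior=paths["behavior"],
                bregma_px=tuple(float(x) for x in _require(t, "bregma_px", where)),
                midline_angle_deg=float(t.get("midline_angle_deg", 0.0)),
                interstim_ms=interstim,
            )
        )
    calib = doc.get("calibration_behavior")
    calib_path = None
    if calib is not None:
        calib_path = root / calib
        if not calib_path.exists():
            raise MissingFileError(f"manifest.calibration_behavior: file not found: {calib_path}")
    return SessionManifest(
        session_id=str(doc["session_id"]),
        mouse_id=str(doc["mouse_id"]),
        condition=condition,
        frame_rate=float(doc["frame_rate"]),
        n_frames=int(doc["n_frames"]),
        dark_frames=tuple(int(x) for x in doc["dark_frames"]),
        pixel_size_um_binned=float(doc["pixel_size_um_binned"]),
        bin_factor=int(doc["bin_factor"]),
        trials=trials,
        calibration_behavior=calib_path,
        root=root,
    )


def read_stack(
    path: str | Path,
    expect_frames: int | None = None,
    expect_dtype: np.dtype | str | None = None,
) -> np.ndarray:
    """Read a multi-frame TIFF, validating frame count and dtype."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if expect_frames is not None and arr.shape[0] != expect_frames:
        raise FrameCountError(
            f"{path}: {arr.shape[0]} frames, manifest declares {expect_frames}"
        )
    if expect_dtype is not None and arr.dtype != np.dtype(expect_dtype):
        raise DtypeError(f"{path}: dtype {arr.dtype}, expected {expect_dtype}")
    return arr


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One configuration object holding every analysis window and threshold."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    vessel_method: str = "otsu"  # or "fixed"
    vessel_threshold: float | None = None  # counts, for the fixed method
    movement_threshold_pct: float = 0.5
    movement_guard_ms: float = 100.0
    include_movement: bool = False
    inclusion_sd_factor: float = 2.0
    paired_baseline_frames: int = 2
    map_scale_pct: float = 0.5
    render_times_ms: tuple[float, ...] = (-30.0, 0.0, 60.0, 120.0, 180.0)
    make_maps: bool = True
    render_maps: bool = False
    layout_path: str | None = None  # replaces the packaged region polygons

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        pp = doc.pop("preprocess", {})
        for k in ("baseline_window", "r0_window", "hb_band", "gain_clip"):
            if k in pp:
                pp[k] = tuple(pp[k])
        if "render_times_ms" in doc:
            doc["render_times_ms"] = tuple(doc["render_times_ms"])
        return cls(preprocess=PreprocessConfig(**pp), **doc)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# provenance structural schema: key -> required python type
PROVENANCE_SCHEMA: dict[str, type] = {
    "package": str,
    "version": str,
    "config_hash": str,
    "seed": int,
    "session_id": str,
    "condition": str,
    "config": dict,
    "trials": dict,
    "failed_trials": dict,
    "warnings": list,
}


def validate_provenance(doc: dict) -> None:
    """Structural validation of a provenance record (keys and types)."""
    for key, typ in PROVENANCE_SCHEMA.items():
        if key not in doc:
            raise ValueError(f"provenance missing key {key!r}")
        if not isinstance(doc[key], typ):
            raise ValueError(f"provenance key {key!r}: expected {typ.__name__}")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _trial_layout(manifest: SessionManifest, trial: TrialSpec, config: PipelineConfig) -> AtlasLayout:
    if config.layout_path:
        base = AtlasLayout.from_yaml(config.layout_path)
        regions = base.regions
    else:
        regions = None
    if regions is None:
        return default_layout(
            bregma_px=trial.bregma_px,
            pixel_size_um=manifest.pixel_size_um_binned,
            midline_angle_deg=trial.midline_angle_deg,
        )
    return AtlasLayout(
        regions=regions,
        bregma_px=trial.bregma_px,
        midline_angle_deg=trial.midline_angle_deg,
        pixel_size_um=manifest.pixel_size_um_binned,
    )


def run_pipeline(
    manifest: SessionManifest | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = "widevolt_out",
    seed: int = 0,
) -> dict:
    """Run the full analysis on a session and write all outputs.

    Stage order is fixed: movement classification first; only quiet trials
    (unless ``include_movement``) proceed through preprocessing, registration,
    traces, metrics/adaptation, and maps.  A stage failure aborts that trial,
    not the session; failed trials are enumerated in the provenance record.
    Reruns with identical inputs, config and seed are byte-identical.
    """
    if not isinstance(manifest, SessionManifest):
        manifest = load_session(manifest)
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stim0 = manifest.trials[0].stim_frames[0] - 1
    calib = None
    if manifest.calibration_behavior is not None:
        calib_stack = read_stack(manifest.calibration_behavior)
        ref = stim0 if stim0 < calib_stack.shape[0] else calib_stack.shape[0] // 2
        calib = calibrate_noise(calib_stack, ref_index=ref)

    movement_rows, trace_rows, metric_rows, adapt_rows = [], [], [], []
    maps: list[VoltageMap] = []
    trial_prov: dict[str, dict] = {}
    failed: dict[str, str] = {}
    all_warnings: list[str] = []

    for trial in manifest.trials:
        try:
            stim_idx0 = trial.stim_frames[0] - 1
            label = "quiet"
            near = False
            if calib is not None:
                behavior = read_stack(trial.behavior, expect_frames=manifest.n_frames)
                idx, fr, trunc = changed_pixel_fraction(behavior, stim_idx0, calib)
                mres = classify_trial(
                    fr, idx, stim_idx0, manifest.frame_rate,
                    cfg.movement_threshold_pct, cfg.movement_guard_ms, trunc,
                )
                label, near = mres.label, mres.near_stim
                movement_rows.append(
                    {
                        "trial_id": trial.trial_id,
                        "label": label,
                        "max_changed_pct": float(fr.max()),
                        "near_stim": near,
                        "threshold_pct": cfg.movement_threshold_pct,
                    }
                )
            if label == "movement" and not cfg.include_movement:
                trial_prov[trial.trial_id] = {"status": "excluded-movement"}
                continue

            donor = read_stack(trial.donor, expect_frames=manifest.n_frames)
            acceptor = read_stack(trial.acceptor, expect_frames=manifest.n_frames)
            seq = DualChannelSequence(
                donor=donor,
                acceptor=acceptor,
                frame_rate=manifest.frame_rate,
                dark_frames=manifest.dark_frames,
                stim_frames=trial.stim_frames,
                pixel_size_um=manifest.pixel_size_um_binned / manifest.bin_factor,
            )
            # vessel mask from a binned raw (pre-offset-subtraction) lit donor frame
            lit_ref = bin_spatial(
                donor[(manifest.dark_frames[1] + stim_idx0) // 2].astype(float),
                cfg.preprocess.bin_factor,
            )
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                vessel = make_vessel_mask(
                    lit_ref, method=cfg.vessel_method, threshold=cfg.vessel_threshold
                )
                ratio, prov = preprocess(seq, cfg.preprocess, vessel_mask=vessel)
            all_warnings.extend(f"{trial.trial_id}: {w.message}" for w in wlist)

            layout = _trial_layout(manifest, trial, cfg)
            labels, names = rasterize_atlas(layout, ratio.drr.shape[1:])
            paired = trial.stimulus_type in PAIRED_TYPES
            for region in names:
                try:
                    tr = region_trace(ratio, labels, names, region)
                except ValueError as e:
                    all_warnings.append(f"{trial.trial_id}/{region}: {e}")
                    continue
                t_ms = tr.time_ms
                for k in range(len(tr.drr)):
                    trace_rows.append(
                        {
                            "trial_id": trial.trial_id,
                            "region": region,
                            "frame": k + 1,
                            "time_ms": t_ms[k],
                            "drr_pct": tr.drr[k],
                            "n_pixels": tr.n_pixels,
                        }
                    )
                if paired:
                    res = paired_pulse(
                        tr,
                        baseline_frames=cfg.paired_baseline_frames,
                        trial_id=trial.trial_id,
                    )
                    adapt_rows.append(dataclasses.asdict(res))
                else:
                    m = compute_metrics(tr, trial_id=trial.trial_id)
                    metric_rows.append(dataclasses.asdict(m))
            if cfg.make_maps and not paired:
                vm = trial_map(
                    ratio,
                    bregma_px=trial.bregma_px,
                    midline_angle_deg=trial.midline_angle_deg,
                )
                vm.scale_pct = cfg.map_scale_pct
                maps.append(vm)
            trial_prov[trial.trial_id] = {"status": "ok", **prov}
        except Exception as e:  # noqa: BLE001 - trial failure must not kill the session
            failed[trial.trial_id] = f"{type(e).__name__}: {e}"
            trial_prov[trial.trial_id] = {"status": "failed"}

    results = {
        "movement": pd.DataFrame(movement_rows),
        "traces": pd.DataFrame(trace_rows),
        "metrics": pd.DataFrame(metric_rows),
        "adaptation": pd.DataFrame(adapt_rows),
        "maps": maps,
        "provenance": {
            "package": "widevolt",
            "version": __version__,
            "config_hash": cfg.hash(),
            "seed": int(seed),
            "session_id": manifest.session_id,
            "condition": manifest.condition,
            "config": cfg.to_dict(),
            "trials": trial_prov,
            "failed_trials": failed,
            "warnings": all_warnings,
        },
    }
    write_outputs(results, out, cfg)
    return results


def _csv_header(cfg: PipelineConfig, seed_line: str) -> str:
    return f"# widevolt {__version__} config_hash={cfg.hash()} {seed_line}\n"


def write_outputs(results: dict, out_dir: str | Path, config: PipelineConfig | None = None) -> None:
    """Write tidy CSVs, maps, provenance and the data dictionary."""
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = results["provenance"]
    header = _csv_header(cfg, f"seed={prov.get('seed', 0)}")

    for name in ("movement", "traces", "metrics", "adaptation"):
        df: pd.DataFrame = results[name]
        p = out / f"{name}.csv"
        with open(p, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        if name == "metrics" and df.empty:
            warnings.warn("metrics table is empty (no included trials)", stacklevel=2)

    # session summary: mean +- SEM per region over included trials
    mdf: pd.DataFrame = results["metrics"]
    if not mdf.empty:
        inc = mdf[mdf["included"]]
        g = inc.groupby("region")
        summary = g.agg(
            n_trials=("peak_amp", "size"),
            peak_amp_mean=("peak_amp", "mean"),
            peak_amp_sem=("peak_amp", "sem"),
            peak_time_mean=("peak_time_ms", "mean"),
            peak_time_sem=("peak_time_ms", "sem"),
            hyp_amp_mean=("hyp_amp", "mean"),
            decay50_mean=("decay50_ms", "mean"),
        ).reset_index()
    else:
        summary = pd.DataFrame()
    with open(out / "summary.csv", "w") as fh:
        fh.write(header)
        summary.to_csv(fh, index=False)

    maps = results.get("maps") or []
    if maps:
        avg = average_aligned_maps(maps)
        tifffile.imwrite(out / "average_map.tif", avg.data.astype(np.float32))
        tifffile.imwrite(out / "average_map_ntrials.tif", avg.n_trials.astype(np.int32))
        (out / "average_map.json").write_text(
            json.dumps(
                {
                    "bregma_px": list(avg.bregma_px),
                    "midline_angle_deg": avg.midline_angle_deg,
                    "pixel_size_um": avg.pixel_size_um,
                    "frame_rate": avg.frame_rate,
                    "stim_index": int(avg.stim_index),
                    "scale_pct": avg.scale_pct,
                    "n_maps": len(maps),
                },
                indent=1,
                sort_keys=True,
            )
        )
        if cfg.render_maps:
            render_map_frames(avg, cfg.render_times_ms, out / "map_frames")

    (out / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True, default=str))
    (out / "data_dictionary.md").write_text(DATA_DICTIONARY)


DATA_DICTIONARY = """\
# Output data dictionary

All CSVs start with one `#` comment line recording package version,
configuration hash and seed (read with `pandas.read_csv(..., comment='#')`).

## traces.csv
- trial_id: trial identifier from the manifest
- region: atlas region name (S1FL, S1HL, S1BF, M1, M2)
- frame: 1-based frame index
- time_ms: time relative to the (first) stimulus onset, ms
- drr_pct: spatially averaged %dR/R of the region's valid pixels
- n_pixels: number of valid pixels averaged

## metrics.csv (single-stimulation trials)
- baseline_mean / baseline_sd: %dR/R over the 10 frames before the stimulus
- peak_amp: max response 20-100 ms post-stimulus, % relative to baseline
- peak_time_ms: time of that maximum, ms post-stimulus
- included: peak_amp >= 2 x baseline_sd (inclusion rule)
- hyp_amp: magnitude (%) of the below-baseline minimum between the peak and
  300 ms (0 if never below baseline); hyp_time_ms: its time
- decay50_ms: time to decay to 50 % of peak amplitude (NaN if not reached)

## adaptation.csv (double-stimulation trials)
- interstim_ms: inter-stimulus interval
- amp1 / amp2: evoked amplitudes (%) against each stimulus' own 20 ms baseline
- ratio: amp2/amp1 peak depolarisation ratio (NaN when amp1 <= 0)

## movement.csv
- label: quiet | movement (changed-pixel fraction vs the 0.5 % separator)
- max_changed_pct: largest changed-pixel fraction in [stim-10, stim+60] frames
- near_stim: exceedance within +-100 ms of the stimulus

## summary.csv
Mean +- SEM of the metrics per region over included quiet trials.

## average_map.tif / average_map_ntrials.tif / average_map.json
Trial-averaged, bregma-aligned dR stack (%, float32; NaN = no data),
per-pixel contributing-trial counts, and alignment metadata.
"""
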