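"""End-to-end synthetic study designs.

Three study analogs, mirroring how a multi-contrast vessel-wall protocol is
validated in practice:

* **scan-rescan repeatability** -- every subject is imaged twice (fresh
  noise, sub-voxel repositioning); lumen/wall area and wall thickness are
  measured per slice and pooled into ICC / CoV / Bland-Altman tables per
  (contrast, acceleration factor);
* **sharpness sweep** -- wall-lumen edge sharpness of the T1w-analog as a
  function of the CS factor;
* **observer reproducibility** -- a single session per subject is contoured
  repeatedly by simulated readers (constant radial bias + vertex noise) to
  give intra- and inter-observer tables;
* **thickness comparison** -- paired t-test of per-subject mean wall
  thickness, accelerated vs non-accelerated.

All randomness flows through a single master seed via
``numpy.random.SeedSequence`` spawning (one branch per subject, then per
stage), so every table is bit-reproducible; the sampling mask is drawn per
(subject, contrast, R) and shared by both sessions ("fixed per protocol").
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kspace import KSpaceData, apply_mask, combine_masks, encode, make_cs_mask, make_pi_mask
from .morphometry import mean_sharpness, measure_vessel, reformat_axial
from .phantom import (
    PhantomSpec,
    PlaqueBump,
    build_phantom,
    ground_truth_geometry,
    jitter_geometry,
    observer_contours,
)
from .recon import ReconParams, reconstruct
from .stats import PairedMeasurements, RepeatabilityResult, paired_ttest, repeatability_summary

__all__ = [
    "ExperimentConfig",
    "StudyReport",
    "run_repeatability",
    "run_sharpness_sweep",
    "run_observer_study",
    "run_thickness_comparison",
]

METRICS = ("lumen_area", "wall_area", "wall_thickness")


@dataclass
class ExperimentConfig:
    """Study configuration; defaults are the volunteer-analog conditions.

    ``cohort="patient"`` switches to thicker walls with a focal plaque bump
    and a wider branch separation.  ``pi_factors`` maps each contrast to its
    uniform parallel-imaging comb (None = CS only), mirroring protocols that
    reserve the parallel-imaging acceleration for the PDw/T2w acquisitions.
    """

    n_subjects: int = 12
    cohort: str = "volunteer"
    contrasts: tuple[str, ...] = ("t1w", "pdw", "t2w")
    cs_factors: tuple[float, ...] = (1.0, 1.5, 2.0)
    pi_factors: dict = field(
        default_factory=lambda: {"t1w": None, "pdw": (2, 1), "t2w": (2, 1)}
    )
    grid_shape: tuple[int, int, int] = (48, 96, 40)
    voxel_mm: tuple[float, float, float] = (0.625, 0.625, 1.4)
    center_size: tuple[int, int] = (32, 32)
    density_sd_frac: float = 0.25
    noise_sd: float = 0.05
    translation_sd_mm: float = 0.5
    radius_sd_mm: float = 0.02
    # each sequence/acceleration is its own acquisition: small within-visit
    # repositioning between acquisitions (translation only; no true change)
    acquisition_translation_sd_mm: float = 0.3
    # between-subject geometry variation (gives the ICC its signal)
    lumen_radius_mean_mm: float = 3.0
    lumen_radius_sd_mm: float = 0.3
    wall_thickness_mean_mm: float = 1.0
    wall_thickness_sd_mm: float = 0.12
    bifurcation_z_mm: float = 7.0
    # observer model
    reader_bias_mm: tuple[float, float] = (0.0, 0.1)
    vertex_noise_sd_mm: float = 0.1
    n_vertices: int = 64
    # measurement windows
    offset_mm: float = 5.0
    n_slices: int = 5
    pooling: str = "slice"  # or "artery"
    icc_model: str = "icc2"
    recon: ReconParams = field(default_factory=ReconParams)
    recon_dtype: str = "complex64"
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if any(r < 1 for r in self.cs_factors):
            raise ValueError("cs_factors must be >= 1")
        if self.cohort not in ("volunteer", "patient"):
            raise ValueError("cohort must be 'volunteer' or 'patient'")
        if self.pooling not in ("slice", "artery"):
            raise ValueError("pooling must be 'slice' or 'artery'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "recon" in raw and isinstance(raw["recon"], dict):
            raw["recon"] = ReconParams(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw["recon"].items()})
        for key in ("contrasts", "cs_factors", "grid_shape", "voxel_mm", "center_size", "reader_bias_mm"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "pi_factors" in raw:
            raw["pi_factors"] = {k: (tuple(v) if v else None) for k, v in raw["pi_factors"].items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pi_factors"] = {k: (list(v) if v else None) for k, v in self.pi_factors.items()}
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Measurement table, per-cell repeatability results, and provenance."""

    measurements: pd.DataFrame
    results: pd.DataFrame
    cells: dict  # (contrast, R, metric[, comparison]) -> RepeatabilityResult
    provenance: dict

    def save(self, out_dir: str | Path, stem: str = "study") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(out / f"{stem}_measurements.csv", index=False)
        self.results.to_csv(out / f"{stem}_results.csv", index=False)
        (out / f"{stem}_provenance.json").write_text(json.dumps(self.provenance, indent=2, default=str))


# ---------------------------------------------------------------------------
# seeding helpers
# ---------------------------------------------------------------------------

def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _subject_spec(config: ExperimentConfig, rng: np.random.Generator) -> PhantomSpec:
    """Draw one subject's geometry from the cohort's population ranges."""
    if config.cohort == "patient":
        wall_mean, wall_sd = 2.2, 0.3
        wall_clip = (1.6, 2.7)
        lumen_clip = (2.2, 3.3)
        bump = PlaqueBump(
            amplitude_mm=float(np.clip(rng.normal(0.6, 0.3), 0.0, 0.8)),
            z_mm=config.bifurcation_z_mm - config.offset_mm,  # on the CCA window
            sigma_mm=3.0,
        )
        branch_sep = 12.0
    else:
        wall_mean, wall_sd = config.wall_thickness_mean_mm, config.wall_thickness_sd_mm
        wall_clip = (0.7, 1.4)
        lumen_clip = (2.2, 3.8)
        bump = PlaqueBump()
        branch_sep = 9.0
    lumen = float(np.clip(rng.normal(config.lumen_radius_mean_mm, config.lumen_radius_sd_mm), *lumen_clip))
    wall = float(np.clip(rng.normal(wall_mean, wall_sd), *wall_clip))
    return PhantomSpec(
        grid_shape=config.grid_shape,
        voxel_mm=config.voxel_mm,
        lumen_radius_mm=lumen,
        wall_thickness_mm=wall,
        bifurcation_z_mm=config.bifurcation_z_mm,
        branch_separation_mm=branch_sep,
        plaque=bump,
        n_coils=4,
        noise_sd=config.noise_sd,
    )


def _crop_ranges(geometry, config: ExperimentConfig, margin_mm: float = 3.5):
    df = geometry.per_slice
    x_lo = float((df.cx_mm - df.outer_radius_mm).min()) - margin_mm
    x_hi = float((df.cx_mm + df.outer_radius_mm).max()) + margin_mm
    y_lo = float((df.cy_mm - df.outer_radius_mm).min()) - margin_mm
    y_hi = float((df.cy_mm + df.outer_radius_mm).max()) + margin_mm
    z_pad = config.offset_mm + config.n_slices * 0.3 / 2 + 1.5
    z_lo = geometry.bifurcation_z_mm - z_pad
    z_hi = geometry.bifurcation_z_mm + z_pad
    return (x_lo, x_hi), (y_lo, y_hi), (z_lo, z_hi)


def _reconstruct_volume(k_full: KSpaceData, mask, config: ExperimentConfig):
    """Apply the mask (None = fully sampled) and reconstruct."""
    if mask is None:
        return reconstruct(k_full, config.recon)
    ku = apply_mask(k_full, mask)
    if config.recon_dtype == "complex64":
        ku = KSpaceData(
            data=ku.data.astype(np.complex64), mask=ku.mask, noise_sd=ku.noise_sd, voxel_mm=ku.voxel_mm
        )
    return reconstruct(ku, config.recon)


def _protocol_mask(config: ExperimentConfig, contrast: str, R: float, seed: int):
    """Sampling mask for one (contrast, R) protocol cell; None = full."""
    phase_shape = config.grid_shape[1:]
    pi = config.pi_factors.get(contrast)
    cs = make_cs_mask(phase_shape, R, config.center_size, config.density_sd_frac, seed) if R > 1 else None
    if pi is None or tuple(pi) == (1, 1):
        return cs
    pim = make_pi_mask(phase_shape, tuple(pi), config.center_size)
    if cs is None:
        return pim
    return combine_masks(cs, pim)


# ---------------------------------------------------------------------------
# scan-rescan repeatability
# ---------------------------------------------------------------------------

def _measure_session(
    spec: PhantomSpec,
    config: ExperimentConfig,
    session_id: str,
    noise_ss: np.random.SeedSequence,
    masks: dict,
) -> pd.DataFrame:
    """Encode, reconstruct and measure one scan session.

    Every (contrast, R) cell is its own acquisition: the subject is
    repositioned slightly (translation only) and the noise realisation is
    fresh, as in a protocol where each sequence is run separately.
    """
    rows = []
    noise_children = noise_ss.spawn(len(config.contrasts))
    for contrast, n_ss in zip(config.contrasts, noise_children):
        arm_children = n_ss.spawn(len(config.cs_factors))
        for R, arm_ss in zip(config.cs_factors, arm_children):
            pos_ss, enc_ss = arm_ss.spawn(2)
            arm_spec = jitter_geometry(
                spec, _seed_int(pos_ss), config.acquisition_translation_sd_mm, 0.0
            )
            images, geometry, sens = build_phantom(arm_spec, contrasts=(contrast,))
            xr, yr, zr = _crop_ranges(geometry, config)
            k_full = encode(
                images[contrast], sens, noise_sd=config.noise_sd, seed=_seed_int(enc_ss), voxel_mm=spec.voxel_mm
            )
            res = _reconstruct_volume(k_full, masks[(contrast, R)], config)
            ax = reformat_axial(
                res.combined, spec.voxel_mm, x_range_mm=xr, y_range_mm=yr, z_range_mm=zr
            )
            mm = measure_vessel(ax, geometry, config.offset_mm, config.n_slices, session_id=session_id)
            df = mm.per_slice
            if len(df) == 0:
                continue
            df = df.assign(contrast=contrast, R=R, session=session_id)
            rows.append(df)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def _pool_pairs(merged: pd.DataFrame, metric: str, pooling: str) -> PairedMeasurements:
    if pooling == "artery":
        g = merged.groupby(["subject", "segment"])[[f"{metric}_1", f"{metric}_2"]].mean().reset_index()
    else:
        g = merged
    return PairedMeasurements(g[f"{metric}_1"].to_numpy(), g[f"{metric}_2"].to_numpy())


def run_repeatability(config: ExperimentConfig) -> StudyReport:
    """Scan-rescan study: every subject imaged twice, measurements pooled
    into ICC / CoV / Bland-Altman / paired-t tables per (contrast, R, metric)."""
    master = np.random.SeedSequence(config.master_seed)
    all_rows = []
    for subject, subj_ss in enumerate(master.spawn(config.n_subjects)):
        geom_ss, mask_ss, s1_ss, s2_ss = subj_ss.spawn(4)
        spec = _subject_spec(config, np.random.default_rng(geom_ss))
        mask_children = mask_ss.spawn(len(config.contrasts) * len(config.cs_factors))
        masks = {}
        for i, contrast in enumerate(config.contrasts):
            for j, R in enumerate(config.cs_factors):
                seed = _seed_int(mask_children[i * len(config.cs_factors) + j])
                masks[(contrast, R)] = _protocol_mask(config, contrast, R, seed)
        for session_id, sess_ss in (("scan1", s1_ss), ("scan2", s2_ss)):
            jit_ss, noise_ss = sess_ss.spawn(2)
            sess_spec = jitter_geometry(
                spec, _seed_int(jit_ss), config.translation_sd_mm, config.radius_sd_mm
            )
            df = _measure_session(sess_spec, config, session_id, noise_ss, masks)
            if len(df):
                all_rows.append(df.assign(subject=subject))
    measurements = pd.concat(all_rows, ignore_index=True)

    keys = ["subject", "contrast", "R", "segment", "slice"]
    s1 = measurements[measurements.session == "scan1"].set_index(keys)
    s2 = measurements[measurements.session == "scan2"].set_index(keys)
    merged = s1.join(s2, how="inner", lsuffix="_1", rsuffix="_2").reset_index()

    cells = {}
    result_rows = []
    for (contrast, R), group in merged.groupby(["contrast", "R"]):
        for metric in METRICS:
            pairs = _pool_pairs(group, metric, config.pooling)
            rep = repeatability_summary(pairs, icc_model=config.icc_model)
            cells[(contrast, R, metric)] = rep
            result_rows.append(_result_row(contrast, R, metric, rep))
    results = pd.DataFrame(result_rows)
    provenance = {
        "design": "scan_rescan_repeatability",
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "software_version": __version__,
        "pooling": config.pooling,
        "icc_model": config.icc_model,
    }
    return StudyReport(measurements=measurements, results=results, cells=cells, provenance=provenance)


def _result_row(contrast, R, metric, rep: RepeatabilityResult, **extra) -> dict:
    row = {
        "contrast": contrast,
        "R": R,
        "metric": metric,
        "icc": rep.icc,
        "icc_lo": rep.icc_ci[0],
        "icc_hi": rep.icc_ci[1],
        "cov_percent": rep.cov_percent,
        "mean_diff": rep.bland_altman[0],
        "loa_lo": rep.bland_altman[1],
        "loa_hi": rep.bland_altman[2],
        "t": rep.ttest[0],
        "p": rep.ttest[1],
        "df": rep.ttest[2],
        "category": rep.category,
        "n": rep.n,
    }
    row.update(extra)
    return row


# ---------------------------------------------------------------------------
# sharpness vs CS factor
# ---------------------------------------------------------------------------

def run_sharpness_sweep(
    config: ExperimentConfig,
    n_angles: int = 8,
    n_boot: int = 200,
) -> pd.DataFrame:
    """Wall-lumen sharpness of the T1w-analog at each CS factor.

    One session per subject; sharpness is the mean over ``n_angles`` radial
    profiles on the central CCA measurement slice.  Returns one row per CS
    factor with the median across subjects and a bootstrap IQR.
    """
    master = np.random.SeedSequence(config.master_seed)
    contrast = "t1w"
    values: dict[float, list[float]] = {R: [] for R in config.cs_factors}
    for subject, subj_ss in enumerate(master.spawn(config.n_subjects)):
        geom_ss, mask_ss, noise_ss = subj_ss.spawn(3)
        spec = _subject_spec(config, np.random.default_rng(geom_ss))
        images, geometry, sens = build_phantom(spec)
        xr, yr, zr = _crop_ranges(geometry, config)
        k_full = encode(images[contrast], sens, config.noise_sd, _seed_int(noise_ss), spec.voxel_mm)
        mask_children = mask_ss.spawn(len(config.cs_factors))
        for R, m_ss in zip(config.cs_factors, mask_children):
            mask = _protocol_mask(config, contrast, R, _seed_int(m_ss))
            res = _reconstruct_volume(k_full, mask, config)
            ax = reformat_axial(res.combined, spec.voxel_mm, x_range_mm=xr, y_range_mm=yr, z_range_mm=zr)
            cca = geometry.segment_rows("CCA").iloc[0]
            sl = ax.slice_of_z(geometry.bifurcation_z_mm - config.offset_mm)
            s = mean_sharpness(
                ax, sl, (float(cca.cx_mm), float(cca.cy_mm)), float(cca.lumen_radius_mm), n_angles
            )
            values[R].append(s)
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 77]))
    rows = []
    for R in config.cs_factors:
        v = np.asarray(values[R])
        boot = np.median(rng.choice(v, size=(n_boot, len(v)), replace=True), axis=1)
        rows.append(
            {
                "R": R,
                "n_subjects": len(v),
                "sharpness_median": float(np.median(v)),
                "sharpness_iqr_lo": float(np.percentile(boot, 25)),
                "sharpness_iqr_hi": float(np.percentile(boot, 75)),
                "sharpness_mean": float(np.mean(v)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# observer reproducibility
# ---------------------------------------------------------------------------

def _contour_metrics(truth, lumen_set, outer_set) -> pd.DataFrame:
    from .morphometry import wall_metrics

    rows = []
    for lc in lumen_set:
        oc = outer_set.get(lc.slice_index, lc.segment)
        m = wall_metrics(lc, oc)
        m.update(segment=lc.segment, slice=lc.slice_index)
        rows.append(m)
    return pd.DataFrame(rows)


def run_observer_study(config: ExperimentConfig) -> StudyReport:
    """Intra- and inter-observer reproducibility of the contour measurements.

    A single session per subject; simulated readers re-contour the same true
    geometry.  Intra-observer pairs share the reader bias but have fresh
    vertex noise; the inter-observer pair differs in the constant radial
    bias as well.  Measurement windows are the standard slice selections.
    """
    master = np.random.SeedSequence(config.master_seed)
    from .morphometry import select_slices

    all_rows = []
    for subject, subj_ss in enumerate(master.spawn(config.n_subjects)):
        geom_ss, obs_ss = subj_ss.spawn(2)
        spec = _subject_spec(config, np.random.default_rng(geom_ss))
        truth = ground_truth_geometry(spec)
        windows = select_slices(
            spec.grid_shape[2], truth.bifurcation_index, spec.voxel_mm[2], config.offset_mm, config.n_slices
        )
        slice_ids = sorted({s for idx in windows.values() for s in idx})
        b1, b2 = config.reader_bias_mm
        readings = [
            ("reader1", "read1", b1),
            ("reader1", "read2", b1),
            ("reader2", "read1", b2),
        ]
        for (reader, read, bias), read_ss in zip(readings, obs_ss.spawn(len(readings))):
            seed = _seed_int(read_ss)
            lum, out = observer_contours(
                truth,
                reader_bias_mm=bias,
                vertex_noise_sd_mm=config.vertex_noise_sd_mm,
                seed=seed,
                n_vertices=config.n_vertices,
                reader_id=reader,
                slice_indices=slice_ids,
            )
            df = _contour_metrics(truth, lum, out)
            df = df.assign(subject=subject, reader=reader, read=read)
            all_rows.append(df)
    measurements = pd.concat(all_rows, ignore_index=True)

    keys = ["subject", "segment", "slice"]
    base = measurements[(measurements.reader == "reader1") & (measurements.read == "read1")].set_index(keys)
    intra = measurements[(measurements.reader == "reader1") & (measurements.read == "read2")].set_index(keys)
    inter = measurements[(measurements.reader == "reader2")].set_index(keys)

    cells = {}
    rows = []
    for comparison, other in (("intra_observer", intra), ("inter_observer", inter)):
        merged = base.join(other, how="inner", lsuffix="_1", rsuffix="_2").reset_index()
        for metric in METRICS:
            pairs = _pool_pairs(merged, metric, config.pooling)
            rep = repeatability_summary(pairs, icc_model=config.icc_model)
            cells[(comparison, metric)] = rep
            rows.append(_result_row("all", np.nan, metric, rep, comparison=comparison))
    results = pd.DataFrame(rows)
    provenance = {
        "design": "observer_reproducibility",
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "software_version": __version__,
        "cohort": config.cohort,
    }
    return StudyReport(measurements=measurements, results=results, cells=cells, provenance=provenance)


# ---------------------------------------------------------------------------
# thickness: accelerated vs non-accelerated
# ---------------------------------------------------------------------------

def run_thickness_comparison(
    config: ExperimentConfig,
    measurements: pd.DataFrame | None = None,
    session: str = "scan1",
) -> pd.DataFrame:
    """Paired t-test of per-subject mean wall thickness, each CS factor
    against the non-accelerated (R = 1) arm of the same contrast.

    Reuses a repeatability study's measurement table when given one;
    otherwise runs the acquisition arms itself.
    """
    if 1.0 not in config.cs_factors:
        raise ValueError("thickness comparison needs the non-accelerated R=1 arm")
    if measurements is None:
        measurements = run_repeatability(config).measurements
    contrast = "t1w" if "t1w" in config.contrasts else config.contrasts[0]
    df = measurements[(measurements.contrast == contrast) & (measurements.session == session)]
    per_subject = (
        df.groupby(["subject", "R"])["wall_thickness"].mean().unstack("R")
    )
    rows = []
    for R in config.cs_factors:
        if R == 1.0:
            continue
        both = per_subject[[1.0, R]].dropna()
        pairs = PairedMeasurements(both[1.0].to_numpy(), both[R].to_numpy())
        try:
            t, p, dof = paired_ttest(pairs)
        except ValueError:
            t, p, dof = 0.0, 1.0, pairs.n - 1  # zero-difference sentinel
        rows.append(
            {
                "contrast": contrast,
                "R": R,
                "n_subjects": pairs.n,
                "mean_noncs_mm": float(both[1.0].mean()),
                "sd_noncs_mm": float(both[1.0].std(ddof=1)),
                "mean_cs_mm": float(both[R].mean()),
                "sd_cs_mm": float(both[R].std(ddof=1)),
                "t": t,
                "p": p,
                "df": dof,
            }
        )
    return pd.DataFrame(rows)
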