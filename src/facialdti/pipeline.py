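"""Configuration, file I/O, grid resampling and end-to-end orchestration.

The pipeline runs simulate -> fit -> track -> MPM -> extract -> stats for a
healthy and a patient cohort on a shared analysis grid, producing the three
group MPMs (healthy-only, patient-only, pooled), a long-format measurement
table and the three comparison tables, plus a JSON run manifest echoing
every parameter, the seed, output hashes and QC counters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import dtifit, groupstats, mpm as mpm_mod, phantom, tracking

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    n_healthy: int = 18
    n_patient: int = 19
    rd_effect: float = phantom.DEFAULT_RD_EFFECT
    ad_effect: float = 1.0
    between_subject_sd: float = 0.08
    between_side_sd: float = 0.03
    affected_side: str = "mixed"
    grid_shape: tuple = phantom.DEFAULT_GRID_SHAPE
    voxel_size: float = phantom.DEFAULT_VOXEL_SIZE  # mm, analysis grid
    ad_true: float = phantom.DEFAULT_AD
    rd_true: float = phantom.DEFAULT_RD
    iso_background: float = 1.0e-3
    s0: float = 1000.0
    snr: float = 30.0  # b=0 SNR; sigma = s0 / snr (snr = 0 -> noiseless)
    n_directions: int = 20
    bvalue: float = 1000.0


@dataclass
class TrackingConfig:
    fa_threshold: float = 0.15
    angle_threshold: float = 60.0
    min_length: float = 2.0
    step_size: float = 0.2
    max_steps: int = 2000
    seed_diameter: float = 5.0   # mm, spherical seed ROIs
    seeds_per_side: int = 2      # spheres along each nerve
    seed_density: int = 1


@dataclass
class MpmConfig:
    rule: str = "strict-majority"  # the only fusion rule implemented


@dataclass
class StatsConfig:
    alpha: float = 0.05


@dataclass
class IoConfig:
    write_subject_volumes: bool = False
    compress: bool = True


@dataclass
class PipelineConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    mpm: MpmConfig = field(default_factory=MpmConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    io: IoConfig = field(default_factory=IoConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"]["grid_shape"] = list(self.phantom.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = {}
        for name, sub in (("phantom", PhantomConfig), ("tracking", TrackingConfig),
                          ("mpm", MpmConfig), ("stats", StatsConfig), ("io", IoConfig)):
            block = dict(d.get(name, {}))
            if name == "phantom" and "grid_shape" in block:
                block["grid_shape"] = tuple(block["grid_shape"])
            kw[name] = sub(**block)
        return cls(seed=int(d.get("seed", 0)), **kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def tracking_params(self) -> tracking.TrackingParams:
        return tracking.TrackingParams(
            fa_threshold=self.tracking.fa_threshold,
            angle_threshold=self.tracking.angle_threshold,
            min_length=self.tracking.min_length,
            step_size=self.tracking.step_size,
            max_steps=self.tracking.max_steps,
        )

    def tissue(self) -> phantom.TissueModel:
        p = self.phantom
        sigma = 0.0 if p.snr == 0 else p.s0 / p.snr
        return phantom.TissueModel(ad_true=p.ad_true, rd_true=p.rd_true,
                                   iso_background=p.iso_background,
                                   s0=p.s0, sigma=sigma)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def save_nifti(path, data: np.ndarray, affine: np.ndarray, dtype=None) -> None:
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine, float)), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_bvals_bvecs(bvals_path, bvecs_path, scheme: phantom.AcquisitionScheme) -> None:
    """FSL dialect: bvals one row; bvecs three rows of N columns."""
    np.savetxt(bvals_path, scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, scheme.bvectors.T, fmt="%.9f")


def read_bvals_bvecs(bvals_path, bvecs_path) -> phantom.AcquisitionScheme:
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return phantom.AcquisitionScheme(bvals, bvecs)  # validates norms etc.


def write_trk(path, streams: list, grid_shape, affine: np.ndarray) -> None:
    """TrackVis .trk with header geometry from the reference grid."""
    tg = nib.streamlines.Tractogram(
        [s.points.astype(np.float32) for s in streams],
        data_per_streamline={"side": np.array(
            [[mpm_mod.LABEL_CODES.get(s.side, 0)] for s in streams], np.float32)},
        affine_to_rasmm=np.eye(4),
    )
    header = {
        "voxel_to_rasmm": np.asarray(affine, np.float32),
        "voxel_sizes": np.linalg.norm(np.asarray(affine)[:3, :3], axis=0).astype(np.float32),
        "dimensions": np.asarray(grid_shape, np.int16),
        "voxel_order": "RAS",
    }
    nib.streamlines.save(nib.streamlines.trk.TrkFile(tg, header), str(path))


def read_trk(path) -> list:
    tf = nib.streamlines.load(str(path))
    sides = tf.tractogram.data_per_streamline.get("side")
    out = []
    for i, pts in enumerate(tf.streamlines):
        code = int(sides[i][0]) if sides is not None else 0
        out.append(tracking.Streamline(
            points=np.asarray(pts, float),
            side=mpm_mod.LABEL_NAMES.get(code, "none")))
    return out


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_to_grid(volume: np.ndarray, source_affine: np.ndarray,
                     target_voxel: float = 0.4, order: int = 1):
    """Resample onto an axis-aligned isotropic grid covering the source FOV.

    ``order=1`` is trilinear (scalar/DWI volumes); ``order=0`` is
    nearest-neighbor (label volumes).  Returns ``(data, target_affine)``;
    when the source is already the target grid the input is returned
    unchanged.
    """
    source_affine = np.asarray(source_affine, float)
    if abs(np.linalg.det(source_affine)) < 1e-15:
        raise ValueError("singular source affine")
    scales = np.linalg.norm(source_affine[:3, :3], axis=0)
    diag = np.allclose(source_affine[:3, :3], np.diag(scales))
    if diag and np.allclose(scales, target_voxel):
        return volume, source_affine
    spatial = np.asarray(volume.shape[:3])
    # voxel-center extent of the source, in world mm
    corners = np.array([[0, 0, 0], spatial - 1], float)
    world = corners @ source_affine[:3, :3].T + source_affine[:3, 3]
    lo, hi = np.minimum(*world), np.maximum(*world)
    n_target = np.floor((hi - lo) / target_voxel).astype(int) + 1
    target_affine = np.eye(4)
    target_affine[:3, :3] = np.eye(3) * target_voxel
    target_affine[:3, 3] = lo
    tgt_idx = np.indices(tuple(n_target)).reshape(3, -1).T.astype(float)
    world_pts = tgt_idx * target_voxel + lo
    src_inv = np.linalg.inv(source_affine)
    src_idx = (world_pts @ src_inv[:3, :3].T + src_inv[:3, 3]).T
    if volume.ndim == 3:
        out = ndimage.map_coordinates(np.asarray(volume, float), src_idx,
                                      order=order, mode="nearest")
        return out.reshape(tuple(n_target)), target_affine
    n_vol = volume.shape[3]
    out = np.empty(tuple(n_target) + (n_vol,))
    for v in range(n_vol):
        out[..., v] = ndimage.map_coordinates(
            np.asarray(volume[..., v], float), src_idx,
            order=order, mode="nearest").reshape(tuple(n_target))
    return out, target_affine


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def default_seed_centers(grid_shape, affine, seeds_per_side: int = 2):
    """Common-space spherical-ROI centers on each nerve's mastoid-like course."""
    centers, sides = [], []
    for side in ("left", "right"):
        geo = phantom.make_centerline(side, grid_shape, affine)
        pts = geo.centerline
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        for frac in np.linspace(0.35, 0.65, seeds_per_side):
            si = frac * s[-1]
            centers.append([np.interp(si, s, pts[:, k]) for k in range(3)])
            sides.append(side)
    return np.asarray(centers), sides


def analyze_subject(subject: phantom.PhantomSubject,
                    scheme: phantom.AcquisitionScheme,
                    seeds: tracking.SeedSet,
                    params: tracking.TrackingParams):
    """fit -> eigendecompose -> scalars -> track -> voxelize for one subject."""
    tensors = dtifit.fit_tensor(subject.dwi, scheme)
    eigs = dtifit.eigendecompose(tensors)
    scalars = dtifit.scalar_maps(eigs)
    streams = tracking.track_all(seeds, eigs, scalars.fa, subject.affine, params)
    label_map = mpm_mod.voxelize_streamlines(streams, scalars.fa.shape, subject.affine)
    return scalars, label_map, streams


@dataclass
class RunManifest:
    config: dict
    seed: int
    started: float
    finished: float = 0.0
    stages: dict = field(default_factory=dict)
    output_hashes: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _cohort_seed(root_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(root_seed)
    return int(ss.spawn(index + 1)[index].generate_state(1)[0] % (2**31 - 1))


def run_analysis(config: PipelineConfig):
    """In-memory end-to-end run; returns (mpms, measurements, tables, info).

    ``info`` carries per-stage QC counters (streamline counts, clamped
    voxels, empty labels) and the subject label maps.
    """
    p = config.phantom
    tissue = config.tissue()
    affine = phantom.default_affine(p.voxel_size)
    scheme = phantom.default_scheme(p.n_directions, p.bvalue)
    h_spec = phantom.healthy_spec(p.n_healthy, rng_seed=_cohort_seed(config.seed, 0),
                                  between_subject_sd=p.between_subject_sd,
                                  between_side_sd=p.between_side_sd)
    p_spec = phantom.CohortSpec(n_subjects=p.n_patient, group="patient",
                                affected_side=p.affected_side,
                                rd_effect=p.rd_effect, ad_effect=p.ad_effect,
                                between_subject_sd=p.between_subject_sd,
                                between_side_sd=p.between_side_sd,
                                rng_seed=_cohort_seed(config.seed, 1))
    cohorts, manifests = {}, {}
    for name, spec in (("healthy", h_spec), ("patient", p_spec)):
        cohorts[name], manifests[name] = phantom.generate_cohort(
            spec, scheme, tissue, p.grid_shape, affine)

    centers, sides = default_seed_centers(p.grid_shape, affine,
                                          config.tracking.seeds_per_side)
    seeds = tracking.make_seeds(centers, config.tracking.seed_diameter,
                                p.grid_shape, affine, sides=sides,
                                density=config.tracking.seed_density)
    params = config.tracking_params()

    per_subject = {"healthy": [], "patient": []}
    info = {"stream_counts": {}, "n_subjects": {}}
    for name in ("healthy", "patient"):
        for subj in cohorts[name]:
            scalars, label_map, streams = analyze_subject(subj, scheme, seeds, params)
            per_subject[name].append((subj, scalars, label_map))
            info["stream_counts"][subj.subject_id] = len(streams)
        info["n_subjects"][name] = len(cohorts[name])

    mpms = mpm_mod.named_mpms([lm for _, _, lm in per_subject["healthy"]],
                              [lm for _, _, lm in per_subject["patient"]])

    frames = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for name, mpm_names in (("healthy", ("healthy", "all")),
                                ("patient", ("patient", "all"))):
            for subj, scalars, _ in per_subject[name]:
                for mn in mpm_names:
                    frames.append(groupstats.extract_indices(
                        scalars, mpms[mn], subj.subject_id, subj.group,
                        subj.affected_side, mpm_name=mn))
    measurements = pd.concat(frames, ignore_index=True)
    info["warnings"] = [str(w.message) for w in caught]
    info["manifests"] = manifests
    if measurements[list(groupstats.INDEXES)].isna().any().any():
        info["tables"] = None
        tables = None
        logger.warning("empty MPM labels: comparison tables skipped")
    else:
        tables = groupstats.build_tables(measurements)
    return mpms, measurements, tables, info


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Full run with artifacts written under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed,
                           started=time.time())
    stage = "simulate/analyze"
    try:
        mpms, measurements, tables, info = run_analysis(config)
        stage = "write"
        affine = phantom.default_affine(config.phantom.voxel_size)
        ext = ".nii.gz" if config.io.compress else ".nii"
        for name, m in mpms.items():
            save_nifti(out / f"mpm_{name}_labels{ext}", m.labels, affine, np.uint8)
            save_nifti(out / f"mpm_{name}_support{ext}", m.support, affine, np.uint16)
        measurements.to_csv(out / "measurements.csv", index=False)
        for cohort, mf in info["manifests"].items():
            mf.to_csv(out / f"manifest_{cohort}.csv", index=False)
        if tables is not None:
            for key, t in tables.items():
                t.to_csv(out / f"{key}.csv", index=False)
            normality = groupstats.normality_screen(measurements)
            normality.to_csv(out / "normality.csv", index=False)
        manifest.stages = {
            "n_subjects": info["n_subjects"],
            "stream_counts": info["stream_counts"],
            "tables_written": tables is not None,
        }
        manifest.warnings = info.get("warnings", [])
        for f in sorted(out.glob("*.csv")):
            manifest.output_hashes[f.name] = _sha256(f)
    except Exception as err:
        manifest.finished = time.time()
        (out / "manifest.json").write_text(manifest.to_json())
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    manifest.finished = time.time()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def write_cohort(subjects: list, scheme: phantom.AcquisitionScheme,
                 manifest: pd.DataFrame, out_dir) -> None:
    """Per-subject DWI (NIfTI), FSL gradient table, truth masks, manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_bvals_bvecs(out / "bvals", out / "bvecs", scheme)
    for s in subjects:
        save_nifti(out / f"{s.subject_id}_dwi.nii.gz", s.dwi.astype(np.float32),
                   s.affine)
        for side in ("left", "right"):
            save_nifti(out / f"{s.subject_id}_mask_{side}.nii.gz",
                       s.truth_masks[side].astype(np.uint8), s.affine)
    manifest.to_csv(out / "manifest.csv", index=False)
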