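"""Synthetic 3D brain-phantom cohorts with implanted group atrophy.

The generator emulates the statistical structure a gray-matter-based
dementia classification study assumes, without any real scans:

* a *template* gray-matter density field inside an ellipsoidal brain mask,
  with a spherical "disease ROI" (a medial-temporal surrogate) strictly
  inside the brain;
* *modulated-GM-like* subject maps built from the generative rule

      I(v) = icv * T(v) * (1 - delta_group * R(v)) * gain_site
             + site_field(v) + noise(v)

  where ``T`` is the template, ``R`` a softened ROI indicator, ``delta``
  the group-wise fractional gray-matter loss, ``icv`` a multiplicative
  head-size factor, and the site terms inject cross-cohort intensity shift;
* *minimal-T1w-like* images: a three-plateau tissue rendering (CSF < GM < WM)
  of the subject map, warped by a random similarity jitter plus a smooth
  deformation and corrupted by a multiplicative bias field, emulating scans
  that were aligned with a similarity transform only;
* an *internal* and an *external* cohort (different group mix, site gain,
  smaller n) bound together in a :class:`Cohort` with a participants TSV.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .images import BrainMask, VolumeImage, save_nifti

GROUPS = ("AD", "CN", "SCD", "MCIc", "MCInc")

# T1w-like plateau intensities (arbitrary units): CSF < GM < WM.
_CSF_LEVEL, _GM_LEVEL, _WM_LEVEL = 0.2, 0.55, 0.85


@dataclass
class ParticipantRecord:
    id: str
    group: str
    cohort: str  # "internal" | "external"
    icv: float
    site: str
    seed: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.icv <= 0:
            raise ValueError("icv must be positive")


@dataclass
class SiteShift:
    """Multiplicative gain plus amplitude of a smooth additive field."""

    gain: float = 1.0
    field_amplitude: float = 0.0


@dataclass
class PhantomConfig:
    """All generator knobs; the defaults define the study conditions.

    ``atrophy_effect`` maps each diagnostic group to the fractional GM
    reduction implanted in the disease ROI. Controls (CN internally, SCD
    externally) carry no effect; MCI converters sit between controls and AD,
    non-converters below converters.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_internal: dict = field(
        default_factory=lambda: {"AD": 100, "CN": 100, "MCIc": 60, "MCInc": 60}
    )
    n_external: dict = field(
        default_factory=lambda: {"AD": 40, "SCD": 30, "MCIc": 15, "MCInc": 25}
    )
    atrophy_effect: dict = field(
        default_factory=lambda: {"AD": 0.30, "CN": 0.0, "SCD": 0.0, "MCIc": 0.18, "MCInc": 0.08}
    )
    roi_radius_fraction: float = 0.16  # ROI radius as fraction of min extent
    roi_soft_sigma: float = 1.0  # voxels; soft edge of the ROI indicator
    noise_sd: float = 0.05
    noise_smooth_sigma: float = 1.2  # voxels
    icv_range: tuple[float, float] = (0.9, 1.1)
    site_shift: dict = field(
        default_factory=lambda: {
            "site_int": SiteShift(1.0, 0.0),
            "site_ext": SiteShift(1.1, 0.02),
        }
    )
    # minimal-T1w representation
    max_rotation_deg: float = 3.0
    max_scale_jitter: float = 0.03
    deformation_amplitude: float = 1.5  # voxels, max displacement
    deformation_sigma: float = 4.0  # voxels, smoothness of the random warp
    bias_field_amplitude: float = 0.1
    bias_smooth_sigma: float = 8.0  # voxels
    seed: int = 0

    def __post_init__(self) -> None:
        for g, d in self.atrophy_effect.items():
            if not 0.0 <= d < 1.0:
                raise ValueError(f"atrophy effect for {g} must be in [0, 1), got {d}")
        if min(self.shape) < 16:
            raise ValueError("shape must be at least 16 voxels per axis")
        for name in ("max_rotation_deg", "max_scale_jitter", "deformation_amplitude",
                     "bias_field_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.site_shift = {
            k: v if isinstance(v, SiteShift) else SiteShift(**v)
            for k, v in self.site_shift.items()
        }

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("shape", "spacing", "icv_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Cohort:
    """Participant records bound to generated image files."""

    records: list
    image_paths: dict  # representation -> {id -> Path}
    out_dir: Path
    template_path: Path
    mask_path: Path
    roi_path: Path
    ground_truth: dict

    def ids(self, cohort: str | None = None, groups: tuple | None = None) -> list[str]:
        return [
            r.id
            for r in self.records
            if (cohort is None or r.cohort == cohort)
            and (groups is None or r.group in groups)
        ]

    def record(self, pid: str) -> ParticipantRecord:
        for r in self.records:
            if r.id == pid:
                return r
        raise KeyError(pid)


def make_template(
    shape: tuple[int, int, int], seed: int, roi_radius_fraction: float = 0.16
) -> tuple[VolumeImage, BrainMask, BrainMask]:
    """Template GM density, brain mask, and disease-ROI mask.

    The template is a smooth random field modulated by a cortical-shell
    profile, restricted to an ellipsoidal brain; values lie in [0, 1]. The
    ROI is a sphere strictly inside the brain, offset toward one temporal
    region. Deterministic given ``seed``.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 16:
        raise ValueError("shape must be at least 16 voxels per axis")
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.44 * s for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    mask = r2 <= 1.0

    # cortical-shell profile: GM density peaks in an outer shell of the brain
    r = np.sqrt(r2)
    shell = np.exp(-((r - 0.75) ** 2) / (2 * 0.18**2))

    fld = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 12.0)
    fld -= fld.min()
    if fld.max() > 0:
        fld /= fld.max()

    tpl = (0.25 + 0.45 * shell + 0.30 * fld) * mask
    tpl = np.clip(tpl, 0.0, 1.0)

    radius = max(3.0, roi_radius_fraction * min(shape))
    roi_center = [c + off * s for c, off, s in zip(center, (0.12, -0.14, -0.10), shape)]
    roi_r2 = sum((g - c) ** 2 for g, c in zip(grids, roi_center))
    roi = roi_r2 <= radius**2
    if not roi.any() or (roi & ~mask).any():
        raise ValueError("shape too small to contain the disease ROI inside the brain")

    template = VolumeImage(tpl)
    return template, BrainMask(mask), BrainMask(roi, affine=template.affine)


def soft_roi(roi_mask: BrainMask, sigma: float = 1.0) -> np.ndarray:
    """Smoothed ROI indicator, rescaled so its core equals 1 exactly."""
    r = ndimage.gaussian_filter(roi_mask.data.astype(float), sigma=sigma)
    return r / r.max()


def roi_core(roi_mask: BrainMask, sigma: float = 1.0) -> np.ndarray:
    """Eroded ROI where the soft indicator is ~1 (for contrast checks)."""
    it = max(1, int(round(2 * sigma)))
    return ndimage.binary_erosion(roi_mask.data, iterations=it)


def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Smooth zero-mean random field normalized to unit max magnitude."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    m = np.abs(f).max()
    return f / m if m > 0 else f


def synth_subject(
    template: VolumeImage,
    roi_mask: BrainMask,
    record: ParticipantRecord,
    config: PhantomConfig,
    brain_mask: BrainMask | None = None,
) -> VolumeImage:
    """Modulated-GM-like subject map from the generative rule."""
    if record.group not in config.atrophy_effect:
        raise ValueError(f"group {record.group!r} has no atrophy effect configured")
    rng = np.random.default_rng(record.seed)
    delta = config.atrophy_effect[record.group]
    R = soft_roi(roi_mask, config.roi_soft_sigma)
    shift = config.site_shift.get(record.site, SiteShift())

    img = record.icv * template.data * (1.0 - delta * R) * shift.gain

    support = brain_mask.data if brain_mask is not None else template.data > 0
    if shift.field_amplitude > 0:
        img = img + shift.field_amplitude * _smooth_unit_field(
            rng, template.shape, config.bias_smooth_sigma
        ) * support
    if config.noise_sd > 0:
        noise = ndimage.gaussian_filter(
            rng.standard_normal(template.shape), sigma=config.noise_smooth_sigma
        )
        noise = noise / noise.std() * config.noise_sd
        img = img + noise * support
    return template.copy_with(np.clip(img, 0.0, None))


def render_three_tissue(subject_gm: VolumeImage) -> VolumeImage:
    """Three-plateau (CSF < GM < WM) T1w-like rendering of a GM map.

    Voxels with high GM density render at the GM plateau; brain voxels with
    low density render as WM (atrophy converts ROI voxels from GM to WM,
    which is what carries the group signal into this representation); a thin
    low-density rim renders as CSF; background stays 0.
    """
    gm = subject_gm.data
    brain = gm > 0
    peak = np.percentile(gm[brain], 99) if brain.any() else 1.0
    lo, hi = 0.15 * peak, 0.45 * peak
    out = np.zeros_like(gm)
    out[brain & (gm < lo)] = _CSF_LEVEL
    out[brain & (gm >= lo) & (gm < hi)] = _WM_LEVEL
    out[brain & (gm >= hi)] = _GM_LEVEL
    return subject_gm.copy_with(out)


def make_bias_field(
    shape, rng: np.random.Generator, amplitude: float, sigma: float
) -> np.ndarray:
    """Multiplicative bias field 1 + amplitude * (smooth unit field)."""
    if amplitude == 0:
        return np.ones(shape)
    return 1.0 + amplitude * _smooth_unit_field(rng, shape, sigma)


def _similarity_matrix(rng: np.random.Generator, config: PhantomConfig) -> np.ndarray:
    """Random rotation (per-axis, bounded) times isotropic scale jitter."""
    angs = np.deg2rad(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg, 3))
    cx, sx = np.cos(angs[0]), np.sin(angs[0])
    cy, sy = np.cos(angs[1]), np.sin(angs[1])
    cz, sz = np.cos(angs[2]), np.sin(angs[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    scale = 1.0 + rng.uniform(-config.max_scale_jitter, config.max_scale_jitter)
    return scale * (rx @ ry @ rz)


def synth_minimal_t1w(
    subject_gm: VolumeImage, record: ParticipantRecord, config: PhantomConfig
) -> VolumeImage:
    """Minimally aligned T1w-like image of one subject.

    Renders three tissue plateaus from the GM map, then resamples through a
    random similarity jitter plus a smooth nonrigid deformation and applies a
    multiplicative bias field. With all amplitudes zero the output equals the
    rendering up to interpolation error. Deterministic given ``record.seed``
    (a fixed offset decouples this randomness from the GM noise draw).
    """
    rng = np.random.default_rng((record.seed + 987654321) % 2**31)
    rendering = render_three_tissue(subject_gm)
    shape = rendering.shape

    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    center = np.array([(s - 1) / 2.0 for s in shape])

    amat = _similarity_matrix(rng, config)
    pts = np.stack([g - c for g, c in zip(grids, center)], axis=0)
    coords = np.tensordot(amat, pts, axes=(1, 0)) + center[:, None, None, None]

    if config.deformation_amplitude > 0:
        disp = np.stack(
            [
                _smooth_unit_field(rng, shape, config.deformation_sigma)
                for _ in range(3)
            ]
        ) * config.deformation_amplitude
        # folding guard: the warp must keep local volume positive
        jac = np.zeros((3, 3) + shape)
        for i in range(3):
            gradi = np.gradient(disp[i])
            for j in range(3):
                jac[i, j] = gradi[j]
        jac[0, 0] += 1.0
        jac[1, 1] += 1.0
        jac[2, 2] += 1.0
        det = (
            jac[0, 0] * (jac[1, 1] * jac[2, 2] - jac[1, 2] * jac[2, 1])
            - jac[0, 1] * (jac[1, 0] * jac[2, 2] - jac[1, 2] * jac[2, 0])
            + jac[0, 2] * (jac[1, 0] * jac[2, 1] - jac[1, 1] * jac[2, 0])
        )
        if det.min() <= 0:
            raise ValueError(
                "deformation amplitude produces folding (non-positive local volume); "
                "reduce deformation_amplitude or increase deformation_sigma"
            )
        coords = coords + disp

    warped = ndimage.map_coordinates(rendering.data, coords, order=1, mode="constant")
    bias = make_bias_field(shape, rng, config.bias_field_amplitude, config.bias_smooth_sigma)
    return rendering.copy_with(warped * bias)


def _record_seeds(config: PhantomConfig, n: int) -> list[int]:
    ss = np.random.SeedSequence(config.seed)
    return [int(s) % 2**31 for s in ss.generate_state(n, dtype=np.uint64)]


def synth_cohort(
    config: PhantomConfig,
    out_dir: str | Path,
    representations: tuple[str, ...] = ("modulated_gm", "minimal_t1w"),
) -> Cohort:
    """Generate internal + external cohorts and write them under ``out_dir``.

    Writes one NIfTI per subject per representation, the template / brain
    mask / ROI mask, a ``participants.tsv`` (id, group, cohort, icv, site,
    seed) and the config as YAML (the ground truth for recovery tests).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    template, mask, roi = make_template(
        config.shape, config.seed, config.roi_radius_fraction
    )

    plan: list[tuple[str, str, str]] = []  # (group, cohort, site)
    for g, n in config.n_internal.items():
        plan += [(g, "internal", "site_int")] * int(n)
    for g, n in config.n_external.items():
        plan += [(g, "external", "site_ext")] * int(n)

    seeds = _record_seeds(config, len(plan) + 1)
    icv_rng = np.random.default_rng(seeds[-1])
    counters: dict[tuple[str, str], int] = {}
    records = []
    for (g, coh, site), seed in zip(plan, seeds):
        k = counters.get((coh, g), 0)
        counters[(coh, g)] = k + 1
        pid = f"{'int' if coh == 'internal' else 'ext'}-{g}-{k:03d}"
        icv = float(icv_rng.uniform(*config.icv_range))
        records.append(ParticipantRecord(pid, g, coh, icv, site, int(seed)))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids")

    image_paths: dict[str, dict[str, Path]] = {rep: {} for rep in representations}
    for rec in records:
        gm = synth_subject(template, roi, rec, config, brain_mask=mask)
        if "modulated_gm" in representations:
            image_paths["modulated_gm"][rec.id] = save_nifti(
                gm, out_dir / f"{rec.id}_modulated_gm.nii.gz"
            )
        if "minimal_t1w" in representations:
            t1w = synth_minimal_t1w(gm, rec, config)
            image_paths["minimal_t1w"][rec.id] = save_nifti(
                t1w, out_dir / f"{rec.id}_minimal_t1w.nii.gz"
            )

    tpl_path = save_nifti(template, out_dir / "template.nii.gz")
    mask_path = save_nifti(mask, out_dir / "brain_mask.nii.gz")
    roi_path = save_nifti(roi, out_dir / "roi_mask.nii.gz")

    tsv = out_dir / "participants.tsv"
    with tsv.open("w") as fh:
        fh.write("id\tgroup\tcohort\ticv\tsite\tseed\n")
        for r in records:
            fh.write(f"{r.id}\t{r.group}\t{r.cohort}\t{r.icv:.6f}\t{r.site}\t{r.seed}\n")
    config.to_yaml(out_dir / "phantom_config.yaml")

    ground_truth = {
        "atrophy_effect": dict(config.atrophy_effect),
        "roi_path": str(roi_path),
        "site_shift": {k: asdict(v) for k, v in config.site_shift.items()},
    }
    return Cohort(
        records=records,
        image_paths=image_paths,
        out_dir=out_dir,
        template_path=tpl_path,
        mask_path=mask_path,
        roi_path=roi_path,
        ground_truth=ground_truth,
    )


def cohort_hash(cohort: Cohort) -> str:
    """Provenance hash over the participants table."""
    h = hashlib.sha256()
    for r in cohort.records:
        h.update(f"{r.id}|{r.group}|{r.cohort}|{r.icv:.6f}|{r.site}|{r.seed}".encode())
    return h.hexdigest()[:16]
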