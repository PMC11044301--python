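"""Synthetic ADC-map cohorts for exercising the quantification pipeline.

Real post-arrest ADC maps are not publicly deposited, so this module
builds phantom cohorts with the statistical structure the analysis
assumes: each subject's masked brain is a three-component mixture of
truncated normals — normal parenchyma, CSF, and low-ADC
hypoxic-ischaemic lesion tissue — where the per-subject lesion burden f
(the mixture weight of the lesion component) is drawn from an
outcome-group-specific Beta distribution.  Poor-outcome subjects carry a
much larger lesion burden, which is what makes ADC-R(x) prognostic.

The phantoms are deliberately simple where simplicity does not matter
for a voxel-count statistic: lesions are rendered as a handful of
contiguous ellipsoidal blobs (ADC-R is spatially blind, but contiguity
keeps the fixtures realistic), the brain mask is an ellipsoid, and no
acquisition noise physics is simulated.

Everything is a pure function of (spec, seed): per-subject random
streams are derived from the master seed by subject counter, so adding
or reordering subjects never changes another subject's image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .quantify import ADCVolume, VoxelFilter

__all__ = [
    "TissueModel",
    "OutcomeGroupParams",
    "SyntheticCohortSpec",
    "SubjectVoxels",
    "default_tissue_models",
    "default_group_params",
    "brain_mask_for_shape",
    "sample_subject_voxels",
    "expected_adc_r",
    "render_volume",
    "generate_cohort",
    "generate_two_site_study",
    "internal_site_spec",
    "external_site_spec",
]

Outcome = Literal["good", "poor"]


@dataclass(frozen=True)
class TissueModel:
    """A truncated-normal ADC distribution for one tissue class.

    ``mean_adc``/``sd_adc`` parameterise the parent normal and
    ``truncation`` the hard support bounds, all in 1e-6 mm^2/s.
    """

    name: str
    mean_adc: float
    sd_adc: float
    truncation: tuple[float, float]

    def __post_init__(self) -> None:
        if self.sd_adc <= 0:
            raise ValueError(f"{self.name}: sd_adc must be > 0")
        lo, hi = self.truncation
        if not lo < hi:
            raise ValueError(f"{self.name}: truncation bounds must satisfy low < high")
        object.__setattr__(self, "truncation", (float(lo), float(hi)))

    @property
    def _dist(self):
        lo, hi = self.truncation
        a = (lo - self.mean_adc) / self.sd_adc
        b = (hi - self.mean_adc) / self.sd_adc
        return sps.truncnorm(a, b, loc=self.mean_adc, scale=self.sd_adc)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._dist.rvs(size=n, random_state=rng)

    def cdf(self, x: float) -> float:
        return float(self._dist.cdf(x))


@dataclass(frozen=True)
class OutcomeGroupParams:
    """Lesion-burden distribution and CSF fraction for one outcome group.

    The per-subject lesion burden f is Beta(lesion_alpha, lesion_beta),
    rejection-truncated to [0, 1 - csf_fraction] so the mixture weights
    (f, csf_fraction, 1 - f - csf_fraction) are always valid; setting
    ``fixed_lesion_fraction`` replaces the Beta by a point mass.
    """

    lesion_alpha: float = 2.0
    lesion_beta: float = 60.0
    csf_fraction: float = 0.10
    fixed_lesion_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.csf_fraction <= 0.3:
            raise ValueError("csf_fraction must lie in [0, 0.3]")
        if self.fixed_lesion_fraction is None:
            if self.lesion_alpha <= 0 or self.lesion_beta <= 0:
                raise ValueError("Beta parameters must be positive")
        else:
            f = self.fixed_lesion_fraction
            if not 0.0 <= f <= 1.0 - self.csf_fraction:
                raise ValueError(
                    f"fixed lesion fraction {f} incompatible with csf_fraction "
                    f"{self.csf_fraction}: mixture weights would be negative"
                )

    def sample_lesion_fraction(self, rng: np.random.Generator) -> float:
        if self.fixed_lesion_fraction is not None:
            return float(self.fixed_lesion_fraction)
        cap = 1.0 - self.csf_fraction
        for _ in range(1000):
            f = float(rng.beta(self.lesion_alpha, self.lesion_beta))
            if f <= cap:
                return f
        raise RuntimeError("lesion-fraction rejection sampling failed to converge")


def default_tissue_models() -> dict[str, TissueModel]:
    """Tissue defaults on the 1e-6 mm^2/s scale.

    Parenchyma sits around 800; CSF around 2600 so that part of it is
    removed by the 2000 exclusion cap, as on real maps; lesion tissue
    sits in the cytotoxic-oedema band around 450.
    """
    return {
        "parenchyma": TissueModel("parenchyma", 800.0, 100.0, (400.0, 1400.0)),
        "csf": TissueModel("csf", 2600.0, 400.0, (1800.0, 3500.0)),
        "lesion": TissueModel("lesion", 450.0, 90.0, (200.0, 700.0)),
    }


def default_group_params() -> dict[str, OutcomeGroupParams]:
    """Good-outcome burden ~ Beta(2, 60) (mean ~3%); poor ~ Beta(4, 8) (mean ~33%)."""
    return {
        "good": OutcomeGroupParams(lesion_alpha=2.0, lesion_beta=60.0, csf_fraction=0.10),
        "poor": OutcomeGroupParams(lesion_alpha=4.0, lesion_beta=8.0, csf_fraction=0.10),
    }


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_good: int
    n_poor: int
    volume_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 7.0
    tissue_models: Mapping[str, TissueModel] = field(default_factory=default_tissue_models)
    group_params: Mapping[str, OutcomeGroupParams] = field(default_factory=default_group_params)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_good < 0 or self.n_poor < 0 or self.n_good + self.n_poor < 1:
            raise ValueError("need n_good >= 0, n_poor >= 0 and at least one subject")
        shape = tuple(int(s) for s in self.volume_shape)
        if len(shape) != 3 or any(s < 8 for s in shape):
            raise ValueError("volume_shape must be three entries, each >= 8")
        object.__setattr__(self, "volume_shape", shape)
        missing = {"parenchyma", "csf", "lesion"} - set(self.tissue_models)
        if missing:
            raise ValueError(f"tissue_models missing classes: {sorted(missing)}")
        if set(self.group_params) != {"good", "poor"}:
            raise ValueError("group_params must have exactly the keys 'good' and 'poor'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        tissues = {
            name: TissueModel(
                name=name,
                mean_adc=t["mean_adc"],
                sd_adc=t["sd_adc"],
                truncation=tuple(t["truncation"]),
            )
            for name, t in raw.get("tissue_models", {}).items()
        } or default_tissue_models()
        groups = {
            name: OutcomeGroupParams(**g) for name, g in raw.get("group_params", {}).items()
        } or default_group_params()
        return cls(
            n_good=raw["n_good"],
            n_poor=raw["n_poor"],
            volume_shape=tuple(raw.get("volume_shape", (24, 24, 24))),
            voxel_size=raw.get("voxel_size", 7.0),
            tissue_models=tissues,
            group_params=groups,
            seed=raw.get("seed", 0),
        )


@dataclass(frozen=True)
class SubjectVoxels:
    """Sampled in-mask voxel values for one subject, split by tissue class."""

    lesion: np.ndarray
    csf: np.ndarray
    parenchyma: np.ndarray
    lesion_fraction: float  # ground-truth mixture weight f

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.lesion, self.csf, self.parenchyma])

    @property
    def n(self) -> int:
        return self.lesion.size + self.csf.size + self.parenchyma.size


def brain_mask_for_shape(shape: tuple[int, int, int]) -> np.ndarray:
    """Deterministic ellipsoidal brain mask filling ~90% of each axis."""
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = np.zeros(shape, dtype=float)
    for g, s in zip(grids, shape):
        c = (s - 1) / 2.0
        a = 0.45 * s
        r2 += ((g - c) / a) ** 2
    return r2 <= 1.0


def _subject_rng(spec: SyntheticCohortSpec, subject_index: int) -> np.random.Generator:
    # counter-based stream: subject i's image is independent of cohort ordering
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(subject_index)]))


def sample_subject_voxels(
    spec: SyntheticCohortSpec,
    outcome: Outcome,
    rng: np.random.Generator,
) -> SubjectVoxels:
    """Draw one subject's in-mask voxel multiset from the tissue mixture.

    The number of voxels equals the ellipsoid-mask size for
    ``spec.volume_shape``; component counts are multinomial with weights
    (f, csf_fraction, 1 - f - csf_fraction), which together with iid
    within-class sampling makes the multiset an iid draw from the
    mixture.
    """
    if outcome not in ("good", "poor"):
        raise ValueError(f"outcome must be 'good' or 'poor', got {outcome!r}")
    params = spec.group_params[outcome]
    f = params.sample_lesion_fraction(rng)
    w = np.array([f, params.csf_fraction, 1.0 - f - params.csf_fraction])
    if np.any(w < 0):
        raise ValueError(f"mixture weights {w.tolist()} are negative")
    n = int(brain_mask_for_shape(spec.volume_shape).sum())
    counts = rng.multinomial(n, w)
    return SubjectVoxels(
        lesion=spec.tissue_models["lesion"].sample(counts[0], rng),
        csf=spec.tissue_models["csf"].sample(counts[1], rng),
        parenchyma=spec.tissue_models["parenchyma"].sample(counts[2], rng),
        lesion_fraction=f,
    )


def expected_adc_r(
    spec: SyntheticCohortSpec,
    f: float,
    x: float,
    csf_fraction: float | None = None,
    filt: VoxelFilter = VoxelFilter(),
) -> float:
    """Closed-form ADC-R(x) (percent) under the mixture, from truncated-normal CDFs.

    This is the analytic oracle for the generator: with lesion burden f
    and mixture weights (f, csf, 1-f-csf), the population value is
    100 * P(ADC in [200, x]) / P(ADC in [200, 2000]).
    """
    if not filt.lower <= x <= filt.upper:
        raise ValueError(f"x={x} outside [{filt.lower}, {filt.upper}]")
    if csf_fraction is None:
        csfs = {g.csf_fraction for g in spec.group_params.values()}
        if len(csfs) != 1:
            raise ValueError(
                "group csf fractions differ; pass csf_fraction explicitly"
            )
        csf_fraction = csfs.pop()
    weights = {
        "lesion": f,
        "csf": csf_fraction,
        "parenchyma": 1.0 - f - csf_fraction,
    }
    if any(w < -1e-12 for w in weights.values()):
        raise ValueError("mixture weights are negative")
    num = 0.0
    den = 0.0
    for name, w in weights.items():
        m = spec.tissue_models[name]
        base = m.cdf(filt.lower)
        num += w * (m.cdf(x) - base)
        den += w * (m.cdf(filt.upper) - base)
    if den <= 0:
        raise ValueError("mixture places no mass in the analysable band")
    return 100.0 * num / den


def _nearest_subset(coords: np.ndarray, centers: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k coords nearest (squared distance) to any center."""
    d = np.min(
        ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    return np.argpartition(d, k - 1)[:k] if k > 0 else np.empty(0, dtype=int)


def render_volume(
    subject: SubjectVoxels,
    spec: SyntheticCohortSpec,
    rng: np.random.Generator,
) -> ADCVolume:
    """Place a subject's voxel multiset into a 3-D grid.

    Lesion voxels form 1-5 contiguous blobs (nearest-to-center regions
    around random seed points); CSF voxels pool around the mask centroid
    (a crude ventricular system); parenchyma fills the rest.  Out-of-mask
    voxels are 0.  The in-mask multiset equals the input multiset
    exactly, so any voxel-count statistic of the rendered volume matches
    the statistic of the raw values.
    """
    mask = brain_mask_for_shape(spec.volume_shape)
    capacity = int(mask.sum())
    if subject.n > capacity:
        raise ValueError(
            f"{subject.n} voxel values exceed brain-mask capacity {capacity} "
            f"for shape {spec.volume_shape}"
        )
    if subject.n < capacity:
        raise ValueError(
            f"{subject.n} voxel values do not fill the brain mask ({capacity} voxels)"
        )
    coords = np.argwhere(mask)
    n_lesion, n_csf = subject.lesion.size, subject.csf.size

    lesion_idx = np.empty(0, dtype=int)
    if n_lesion > 0:
        n_blobs = int(rng.integers(1, 6))
        centers = coords[rng.choice(coords.shape[0], size=n_blobs, replace=False)]
        lesion_idx = _nearest_subset(coords, centers.astype(float), n_lesion)
    remaining = np.setdiff1d(np.arange(coords.shape[0]), lesion_idx, assume_unique=False)

    csf_idx = np.empty(0, dtype=int)
    if n_csf > 0:
        centroid = coords.mean(axis=0, keepdims=True)
        rel = _nearest_subset(coords[remaining].astype(float), centroid, n_csf)
        csf_idx = remaining[rel]
    parenchyma_idx = np.setdiff1d(remaining, csf_idx, assume_unique=False)

    vol = np.zeros(spec.volume_shape, dtype=float)
    for idx, vals in (
        (lesion_idx, subject.lesion),
        (csf_idx, subject.csf),
        (parenchyma_idx, subject.parenchyma),
    ):
        if vals.size:
            ijk = coords[idx]
            vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = rng.permutation(vals)

    affine = np.diag([spec.voxel_size, spec.voxel_size, spec.voxel_size, 1.0])
    return ADCVolume(voxels=vol, affine=affine, mask=mask)


def _sample_covariates(rng: np.random.Generator) -> dict[str, float | int]:
    """Baseline covariates shared across outcome groups (descriptive only)."""
    return {
        "age": int(np.clip(round(rng.normal(58.0, 13.0)), 18, 95)),
        "female_sex": int(rng.random() < 0.27),
        "witnessed_arrest": int(rng.random() < 0.57),
        "shockable_rhythm": int(rng.random() < 0.38),
        "no_flow_time_min": round(float(rng.lognormal(1.2, 0.9)), 1),
        "low_flow_time_min": round(float(rng.lognormal(3.0, 0.6)), 1),
    }


def generate_cohort(
    spec: SyntheticCohortSpec,
    out_dir: str | Path,
    cohort_label: str = "unassigned",
    prefix: str = "sub",
    subject_offset: int = 0,
    with_covariates: bool = True,
) -> pd.DataFrame:
    """Write one synthetic site to disk: NIfTI images, masks, and a manifest.

    Returns the manifest DataFrame; ``manifest.csv`` in ``out_dir``
    carries subject_id, adc_path, mask_path (relative to the manifest),
    outcome_cpc (good -> {1,2}, poor -> {3,4,5}, uniformly) and the
    cohort label, plus baseline covariates unless disabled.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    outcomes = ["good"] * spec.n_good + ["poor"] * spec.n_poor
    for i, outcome in enumerate(outcomes):
        rng = _subject_rng(spec, subject_offset + i)
        subject = sample_subject_voxels(spec, outcome, rng)
        vol = render_volume(subject, spec, rng)
        sid = f"{prefix}{subject_offset + i:04d}"
        adc_name, mask_name = f"{sid}_adc.nii.gz", f"{sid}_mask.nii.gz"
        try:
            nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), vol.affine), out / adc_name)
            nib.save(
                nib.Nifti1Image(vol.mask.astype(np.uint8), vol.affine), out / mask_name
            )
        except OSError as exc:
            raise OSError(f"failed writing image for {sid} under {out}: {exc}") from exc
        cpc = int(rng.integers(1, 3)) if outcome == "good" else int(rng.integers(3, 6))
        row = {
            "subject_id": sid,
            "adc_path": adc_name,
            "mask_path": mask_name,
            "outcome_cpc": cpc,
            "cohort": cohort_label,
        }
        if with_covariates:
            row.update(_sample_covariates(rng))
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


# Group sizes matching the two-site study design this package replicates:
# one site of 320 subjects (split 70/30 into derivation and internal
# validation) and an external site of 128 subjects.


def internal_site_spec(seed: int = 0, **kwargs) -> SyntheticCohortSpec:
    return SyntheticCohortSpec(n_good=114, n_poor=206, seed=seed, **kwargs)


def external_site_spec(seed: int = 1, **kwargs) -> SyntheticCohortSpec:
    return SyntheticCohortSpec(n_good=65, n_poor=63, seed=seed, **kwargs)


def generate_two_site_study(
    internal_spec: SyntheticCohortSpec,
    external_spec: SyntheticCohortSpec,
    out_dir: str | Path,
) -> Path:
    """Write an internal site (cohort 'unassigned', to be split 70/30) and an
    external site (cohort 'external_validation') plus a merged manifest.

    Returns the path of the merged manifest.
    """
    out = Path(out_dir)
    internal = generate_cohort(internal_spec, out / "internal", cohort_label="unassigned", prefix="int")
    external = generate_cohort(external_spec, out / "external", cohort_label="external_validation", prefix="ext")
    internal = internal.assign(
        adc_path="internal/" + internal["adc_path"],
        mask_path="internal/" + internal["mask_path"],
    )
    external = external.assign(
        adc_path="external/" + external["adc_path"],
        mask_path="external/" + external["mask_path"],
    )
    merged = pd.concat([internal, external], ignore_index=True)
    manifest_path = out / "manifest.csv"
    merged.to_csv(manifest_path, index=False)
    return manifest_path
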