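"""Synthetic gray-matter cohort generator.

Emulates the statistical structure of a preterm-birth voxel-based-morphometry
study so the full classification pipeline is testable without MRI data:

* two groups (cases born preterm, labelled +1; term controls, -1) on a small
  common grid with an ellipsoidal "brain" of gray-matter-like intensities;
* a spatially structured group effect with both positive and negative
  regions, graded within cases by a latent severity;
* a global-scale (head size / TIV) confound correlated with group;
* gestational age, birth weight, IQ and an SGA flag linked to severity the
  way the clinical variables of such cohorts are.

Tissue segmentation, nonlinear registration and Jacobian modulation are out
of scope; modulation is emulated by the per-subject global scale factor that
also drives TIV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .volumes import GMVolumeSet, smooth_array, write_volume

__all__ = [
    "EffectRegion",
    "SeverityLink",
    "CohortConfig",
    "CohortTruth",
    "default_regions",
    "generate_cohort",
    "make_effect_map",
    "write_fixture",
    "read_fixture",
    "oracle_projection_accuracy",
]


class ConfigurationError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass(frozen=True)
class EffectRegion:
    """A spherical group-effect region in voxel coordinates."""

    center: tuple
    radius: float
    sign: int
    amplitude: float

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ConfigurationError("effect_regions: sign must be -1 or +1")
        if self.radius < 0 or self.amplitude < 0:
            raise ConfigurationError(
                "effect_regions: radius and amplitude must be nonnegative"
            )


@dataclass(frozen=True)
class SeverityLink:
    """Coefficients mapping latent severity s in (0, 1) to clinical variables.

    Cases: GA = 36 + ga_slope * s (weeks), so severity 0 is borderline
    moderately preterm and severity 1 the earliest birth; birth weight gets
    a GA trend plus ``bw_slope * s`` grams on top; full IQ is
    ``iq_mean + iq_slope * s`` points.  Controls have severity 0.
    """

    ga_slope: float = -12.0
    bw_slope: float = -150.0
    iq_slope: float = -30.0
    iq_mean: float = 102.0


def default_regions(grid_shape=(16, 16, 16)) -> tuple:
    """Two positive and two negative spheres inside the brain ellipsoid,
    scaled from their reference placement on a 16^3 grid."""
    s = np.asarray(grid_shape, dtype=float) / 16.0
    r = float(s.min())
    a = 1.0  # relative amplitude; scaled by CohortConfig.effect_scale
    ref = (
        ((5.0, 5.0, 9.0), 3.2, +1),
        ((10.5, 10.0, 6.5), 2.9, +1),
        ((10.0, 5.5, 9.5), 3.0, -1),
        ((5.5, 10.5, 6.0), 2.6, -1),
    )
    return tuple(
        EffectRegion(tuple(c * f for c, f in zip(center, s)), radius * r, sign, a)
        for center, radius, sign in ref
    )


@dataclass
class CohortConfig:
    """Generator settings; the defaults are the reference study conditions.

    ``effect_scale`` multiplies all region amplitudes (0 gives a null cohort
    with no group effect); its default is calibrated so that an oracle that
    knows the true effect map classifies about 95% of subjects correctly.
    ``tiv_group_gap`` is the fractional deficit in mean global scale of the
    cases (a modest head-size confound).
    """

    n_case: int = 74
    n_control: int = 69
    grid_shape: tuple = (16, 16, 16)
    voxel_size_mm: tuple = (1.5, 1.5, 1.5)
    effect_regions: tuple | None = None  # None -> default_regions(grid_shape)
    effect_scale: float = 0.054
    tiv_group_gap: float = 0.05
    tiv_sd: float = 0.05
    noise_sd: float = 0.2
    smooth_fwhm_mm: float = 6.0
    severity_link: SeverityLink = field(default_factory=SeverityLink)
    sga_fraction: float = 16.0 / 74.0
    iq_missing_frac: float = 0.15
    seed: int = 0

    # distributional constants of the design (documented, not tunable):
    # case GA spans [24, 36] weeks via severity ~ Beta(2, 1.3);
    # control GA ~ Uniform[37, 42] weeks.
    _SEV_BETA = (2.0, 1.3)
    _CONTROL_GA = (37.0, 42.0)

    def __post_init__(self):
        if self.effect_regions is None:
            self.effect_regions = default_regions(self.grid_shape)

    def validate(self) -> None:
        if self.n_case < 2:
            raise ConfigurationError("n_case must be >= 2")
        if self.n_control < 2:
            raise ConfigurationError("n_control must be >= 2")
        if len(self.grid_shape) != 3 or any(int(s) < 2 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be three axes of size >= 2")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigurationError("voxel_size_mm must be positive")
        if not 0.0 <= self.sga_fraction <= 1.0:
            raise ConfigurationError("sga_fraction must lie in [0, 1]")
        if self.smooth_fwhm_mm < 0:
            raise ConfigurationError("smooth_fwhm_mm must be >= 0")
        if self.effect_scale < 0:
            raise ConfigurationError("effect_scale must be >= 0")
        if self.tiv_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("tiv_sd and noise_sd must be >= 0")
        if not 0.0 <= self.iq_missing_frac < 1.0:
            raise ConfigurationError("iq_missing_frac must lie in [0, 1)")
        _check_regions_inside(self.grid_shape, self.effect_regions)

    def expected_ga_means(self) -> tuple:
        """Analytic mean GA (case, control) implied by the design."""
        a, b = self._SEV_BETA
        mean_s = a / (a + b)
        lo, hi = self._CONTROL_GA
        return 36.0 + self.severity_link.ga_slope * mean_s, 0.5 * (lo + hi)


@dataclass
class CohortTruth:
    """Ground truth for parameter-recovery tests: per-subject latent severity
    (0 for controls), the true signed effect map, and the per-subject global
    scale factor that drives TIV."""

    severity: np.ndarray
    effect_map: np.ndarray
    scale: np.ndarray
    template: np.ndarray


def _check_regions_inside(grid_shape, regions) -> None:
    for r in regions:
        if len(r.center) != 3:
            raise ConfigurationError("effect_regions: center must have 3 coordinates")
        for c, dim in zip(r.center, grid_shape):
            if c - r.radius < 0 or c + r.radius > dim - 1:
                raise ConfigurationError(
                    f"effect_regions: sphere at {tuple(r.center)} radius "
                    f"{r.radius} extends outside the {tuple(grid_shape)} grid"
                )


def make_effect_map(grid_shape, effect_regions) -> np.ndarray:
    """Signed effect map: voxels inside a sphere carry sign * amplitude,
    summed where spheres overlap; all other voxels are zero."""
    _check_regions_inside(grid_shape, effect_regions)
    out = np.zeros(tuple(int(s) for s in grid_shape), dtype=np.float64)
    if not effect_regions:
        return out
    grids = np.indices(out.shape).astype(np.float64)
    for r in effect_regions:
        d2 = sum((g - c) ** 2 for g, c in zip(grids, r.center))
        out[d2 <= r.radius**2 + 1e-12] += r.sign * r.amplitude
    return out


def _template(grid_shape) -> np.ndarray:
    """Ellipsoidal gray-matter-like intensity template (peak 0.8)."""
    shape = np.asarray(grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = 0.48 * shape  # ~1900 voxels inside on the default 16^3 grid
    grids = np.indices(tuple(int(s) for s in grid_shape)).astype(np.float64)
    rho2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return 0.8 * np.clip(1.0 - rho2, 0.0, None)


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def generate_cohort(config: CohortConfig):
    """Generate ``(GMVolumeSet, ParticipantTable, CohortTruth)``.

    Deterministic given ``config.seed``.  Cases come first in subject order
    (ids c001.., then t001.. for controls); the participant table's ``group``
    column is +1 for cases and -1 for controls.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    link = config.severity_link
    n_case, n_ctrl = config.n_case, config.n_control
    n = n_case + n_ctrl

    template = _template(config.grid_shape)
    effect = make_effect_map(config.grid_shape, config.effect_regions)
    effect = effect * config.effect_scale

    # latent severity: cases graded in (0, 1), controls exactly 0
    a_beta, b_beta = CohortConfig._SEV_BETA
    sev = np.concatenate([rng.beta(a_beta, b_beta, n_case), np.zeros(n_ctrl)])

    # global scale factor (TIV driver): cases run a modest deficit
    scale = np.concatenate(
        [
            rng.normal(1.0 - config.tiv_group_gap, config.tiv_sd, n_case),
            rng.normal(1.0, config.tiv_sd, n_ctrl),
        ]
    )
    scale = np.clip(scale, 0.5, None)

    # gestational age (continuous weeks) and birth weight (g)
    ga_lo, ga_hi = CohortConfig._CONTROL_GA
    ga = np.empty(n)
    ga[:n_case] = 36.0 + link.ga_slope * sev[:n_case]
    ga[n_case:] = rng.uniform(ga_lo, ga_hi, n_ctrl)

    # SGA cases draw their BW residual (given GA) from the lowest decile;
    # severity is sampled independently, so SGA subjects span severities
    n_sga = int(round(config.sga_fraction * n_case))
    sga = np.zeros(n, dtype=bool)
    if n_sga > 0:
        sga[rng.choice(n_case, size=n_sga, replace=False)] = True
    z = np.empty(n_case)
    z10 = -1.2815515655446004  # 10th-percentile z
    u = rng.uniform(size=n_case)
    p10 = stats.norm.cdf(z10)
    z[sga[:n_case]] = stats.norm.ppf(u[sga[:n_case]] * p10)
    z[~sga[:n_case]] = stats.norm.ppf(p10 + u[~sga[:n_case]] * (1 - p10))

    bw = np.empty(n)
    mean_s = a_beta / (a_beta + b_beta)
    bw[:n_case] = (
        750.0
        + 60.0 * (ga[:n_case] - 24.0)
        + link.bw_slope * (sev[:n_case] - mean_s)
        + 120.0 * z
    )
    bw[:n_case] = np.clip(bw[:n_case], 450.0, 1500.0)
    bw[n_case:] = np.clip(
        3530.0 + 150.0 * (ga[n_case:] - 39.5) + rng.normal(0.0, 320.0, n_ctrl),
        2650.0,
        4700.0,
    )

    sex = np.where(rng.uniform(size=n) < 0.52, "F", "M")
    age = np.clip(rng.normal(14.6, 1.3, n), 12.1, 17.8)

    iq_full = link.iq_mean + link.iq_slope * sev + rng.normal(0.0, 10.0, n)
    iq_verbal = iq_full + rng.normal(0.0, 6.0, n)
    iq_perf = iq_full + rng.normal(0.0, 6.0, n)
    n_missing = int(round(config.iq_missing_frac * n))
    if n_missing > 0:
        miss = rng.choice(n, size=n_missing, replace=False)
        iq_full[miss] = np.nan
        iq_verbal[miss] = np.nan
        iq_perf[miss] = np.nan

    # volumes: scale * (template + severity * effect) + smoothed noise, >= 0
    vols = np.empty((n, *template.shape))
    for i in range(n):
        signal = template + sev[i] * effect
        noise = smooth_array(
            rng.normal(0.0, config.noise_sd, template.shape),
            config.smooth_fwhm_mm,
            config.voxel_size_mm,
        )
        vols[i] = np.clip(scale[i] * signal + noise, 0.0, None)

    ids = [f"c{i + 1:03d}" for i in range(n_case)] + [
        f"t{i + 1:03d}" for i in range(n_ctrl)
    ]
    table = pd.DataFrame(
        {
            "id": ids,
            "group": np.concatenate(
                [np.ones(n_case, dtype=int), -np.ones(n_ctrl, dtype=int)]
            ),
            "ga_weeks": ga,
            "bw_g": bw,
            "sex": sex,
            "age_years": age,
            "sga": sga,
            "iq_full": iq_full,
            "iq_verbal": iq_verbal,
            "iq_perf": iq_perf,
        }
    )
    volset = GMVolumeSet(vols, _affine(config.voxel_size_mm), ids)
    truth = CohortTruth(severity=sev, effect_map=effect, scale=scale, template=template)
    return volset, table, truth


def oracle_projection_accuracy(volset: GMVolumeSet, truth: CohortTruth, labels) -> float:
    """Best threshold accuracy of the true-effect-map projection.

    An oracle that knows the generator's signed effect map scores each
    subject by the inner product of its (generated) volume with that map and
    classifies by the best threshold; its accuracy measures the intrinsic
    separability the generator built in.
    """
    labels = np.asarray(labels)
    m = truth.effect_map.ravel()
    if not np.any(m):
        raise ValueError("effect map is identically zero; no oracle direction")
    proj = volset.data.reshape(volset.n_subjects, -1) @ m
    order = np.argsort(proj)
    y = labels[order]
    n = len(y)
    # accuracy of threshold after position k: predict +1 above, -1 at/below
    n_pos = int((labels == 1).sum())
    best = max(n_pos, n - n_pos)  # trivial all-one-class thresholds
    cum_neg = np.cumsum(y == -1)
    cum_pos = np.cumsum(y == 1)
    for k in range(1, n):
        correct = cum_neg[k - 1] + (n_pos - cum_pos[k - 1])
        best = max(best, correct)
    return best / n


# ---------------------------------------------------------------------------
# fixtures on disk

def write_fixture(volset: GMVolumeSet, table: pd.DataFrame, truth: CohortTruth, directory):
    """Write one NIfTI per subject, participants.tsv and the truth files.

    Returns a dict of written paths; round-trips through
    :func:`read_fixture` / ``volumes.read_volumes``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vol_paths = []
    for i, sid in enumerate(volset.subject_ids):
        p = directory / f"{sid}.nii.gz"
        write_volume(volset.data[i], volset.affine, p)
        vol_paths.append(p)
    table_path = directory / "participants.tsv"
    table.to_csv(table_path, sep="\t", index=False, na_rep="")
    effect_path = directory / "true_effect_map.nii.gz"
    write_volume(truth.effect_map, volset.affine, effect_path)
    truth_path = directory / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "subject_ids": list(volset.subject_ids),
                "severity": truth.severity.tolist(),
                "scale": truth.scale.tolist(),
                "effect_map_file": effect_path.name,
            },
            indent=1,
        )
    )
    return {
        "volumes": vol_paths,
        "participants": table_path,
        "truth": truth_path,
        "effect_map": effect_path,
    }


def read_fixture(directory):
    """Read a written fixture back as ``(GMVolumeSet, ParticipantTable)``."""
    from .volumes import read_volumes

    directory = Path(directory)
    table_path = directory / "participants.tsv"
    if not table_path.exists():
        raise FileNotFoundError(f"participant table not found: {table_path}")
    table = pd.read_csv(table_path, sep="\t")
    table["sga"] = table["sga"].astype(bool)
    paths = [directory / f"{sid}.nii.gz" for sid in table["id"]]
    volset = read_volumes(paths, subject_ids=list(table["id"]))
    return volset, table
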