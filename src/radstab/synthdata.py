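"""Synthetic feature tables and phantom volumes with known ground truth.

This module emulates the two acquisition layouts of a CT feature-stability
study so that every downstream stage (extraction, ICC scoring, selection)
can be exercised end to end without any scan data:

* a **test-retest layout** — an image-quality phantom scanned twice per
  (scanner, protocol) slot, and a 32-subject two-scan cohort;
* a **multi-protocol layout** — 6 phantom protocols x 3 scanners x 2
  timepoints (36 scan slots) and a 104-subject cohort imaged with 3
  clinical protocols, carrying a tumor-volume covariate with a designated
  subset of features built as monotone functions of that volume.

Simulated feature values follow the two-way mixed-effects consistency
model ``y_ij = mu + s_i + r_j + e_ij`` with independent zero-mean normal
subject, rater (column) and residual effects, so the true consistency ICC
``sigma_s^2 / (sigma_s^2 + sigma_e^2)`` is known exactly.

Phantom volumes are a sphere of configurable diameter in a uniform
background at a 4:1 target-to-background signal ratio, with partial-volume
edges from 3x-per-axis supersampling and stationary Gaussian noise whose
standard deviation scales as ``1/sqrt(mA x slice thickness)`` — a
first-order model of CT quantum noise, sufficient to make protocol effects
on features real.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import ImageVolume

__all__ = [
    "VarianceComponents",
    "Protocol",
    "StudyLayout",
    "PhantomSpec",
    "PhantomSlot",
    "ClinicalFixture",
    "RiderFixture",
    "phantom_layout",
    "clinical_layout",
    "rider_layout",
    "simulate_feature_table",
    "generate_phantom_volume",
    "make_study_fixture",
    "make_phantom_fixture",
    "make_clinical_fixture",
    "make_rider_fixture",
    "make_sphere_cohort_fixture",
]

#: Column order of the long-format feature table used across the package.
TABLE_COLUMNS = ["subject", "scanner", "protocol", "timepoint", "feature", "value"]


# ---------------------------------------------------------------------------
# ground-truth variance structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VarianceComponents:
    """Variances of the two-way mixed-effects model, in feature units^2.

    ``rater_var`` produces systematic per-column offsets; the consistency
    ICC ignores them by construction, which the simulator's tests verify.
    """

    subject_var: float
    rater_var: float = 0.0
    residual_var: float = 1.0

    def __post_init__(self) -> None:
        for name in ("subject_var", "rater_var", "residual_var"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def true_icc(self) -> float:
        """Closed-form consistency ICC: sigma_s^2 / (sigma_s^2 + sigma_e^2)."""
        denom = self.subject_var + self.residual_var
        if denom == 0:
            raise ValueError("true ICC undefined: subject_var + residual_var == 0")
        return self.subject_var / denom


# ---------------------------------------------------------------------------
# study layouts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Protocol:
    """One acquisition protocol (the knobs that matter for the noise model)."""

    name: str
    tube_current_ma: float
    slice_thickness_mm: float
    in_plane_mm: float
    contrast: bool = False

    def voxel_spacing_zyx(self) -> tuple[float, float, float]:
        return (self.slice_thickness_mm, self.in_plane_mm, self.in_plane_mm)


@dataclass(frozen=True)
class StudyLayout:
    scanners: tuple[str, ...]
    protocols: tuple[Protocol, ...]
    timepoints: int
    subjects: int

    def __post_init__(self) -> None:
        if self.subjects < 1:
            raise ValueError(f"subjects must be >= 1, got {self.subjects}")
        if self.timepoints < 1:
            raise ValueError(f"timepoints must be >= 1, got {self.timepoints}")
        if not self.scanners or not self.protocols:
            raise ValueError("layout needs at least one scanner and one protocol")

    @property
    def columns(self) -> list[tuple[str, str, int]]:
        """All (scanner, protocol, timepoint) measurement slots, in order."""
        return [
            (s, p.name, t)
            for s in self.scanners
            for p in self.protocols
            for t in range(1, self.timepoints + 1)
        ]

    @property
    def n_slots(self) -> int:
        return len(self.columns)


def _phantom_protocols(scanner: str) -> tuple[Protocol, ...]:
    # 6 protocols: tube current 100/200/300 mA crossed with thin/thick slices.
    # The GE scanner reconstructs 2.5 mm thin slices at 0.9653 mm in-plane;
    # the two Philips scanners use 2 mm at 0.86 mm.
    if scanner == "scanner3":
        thin, thick, inplane = 2.5, 5.0, 0.9653
    else:
        thin, thick, inplane = 2.0, 5.0, 0.86
    out = []
    for i, (ma, thickness) in enumerate(
        [(100, thin), (100, thick), (200, thin), (200, thick), (300, thin), (300, thick)],
        start=1,
    ):
        out.append(Protocol(f"P{i}", ma, thickness, inplane))
    return tuple(out)


def phantom_layout() -> StudyLayout:
    """3 scanners x 6 protocols x test-retest on a single phantom: 36 slots."""
    return StudyLayout(
        scanners=("scanner1", "scanner2", "scanner3"),
        protocols=_phantom_protocols("scanner1"),
        timepoints=2,
        subjects=1,
    )


def clinical_layout(subjects: int = 104) -> StudyLayout:
    """104 patients on one scanner under three clinical protocols."""
    return StudyLayout(
        scanners=("scanner2",),
        protocols=(
            Protocol("BLDCT5", 150, 5.0, 1.17, contrast=True),
            Protocol("WBCECT2", 150, 2.0, 1.17, contrast=True),
            Protocol("NCCTT2", 300, 2.0, 0.87, contrast=False),
        ),
        timepoints=1,
        subjects=subjects,
    )


def rider_layout(subjects: int = 32) -> StudyLayout:
    """32-subject test-retest cohort, single protocol and scanner."""
    return StudyLayout(
        scanners=("GE",),
        protocols=(Protocol("RIDER", 350, 1.25, 0.66),),
        timepoints=2,
        subjects=subjects,
    )


# ---------------------------------------------------------------------------
# feature-table simulation
# ---------------------------------------------------------------------------


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Splittable deterministic stream: one counter per fixture slot."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(key)))


def simulate_feature_table(
    layout: StudyLayout,
    components: VarianceComponents | list[VarianceComponents],
    n_features: int,
    seed: int,
    feature_prefix: str = "f",
    mean: float = 0.0,
) -> pd.DataFrame:
    """Simulate a complete long-format feature table with known ICC structure.

    Each feature f gets its own independent random stream, so any slot can be
    regenerated in isolation.  Values follow ``y_ij = mu + s_i + r_j + e_ij``
    where j runs over all (scanner, protocol, timepoint) slots of the layout.
    """
    if n_features < 1:
        raise ValueError(f"n_features must be >= 1, got {n_features}")
    if layout.subjects < 2:
        raise ValueError(f"layout.subjects must be >= 2 for simulation, got {layout.subjects}")
    cols = layout.columns
    if len(cols) < 2:
        raise ValueError(f"layout must provide >= 2 measurement columns, got {len(cols)}")
    if isinstance(components, VarianceComponents):
        components = [components] * n_features
    if len(components) != n_features:
        raise ValueError(
            f"components list length {len(components)} != n_features {n_features}"
        )

    n, k = layout.subjects, len(cols)
    width = max(3, len(str(n_features - 1)))
    frames = []
    for f, comp in enumerate(components):
        rng = _rng(seed, f)
        s = rng.normal(0.0, np.sqrt(comp.subject_var), size=n)
        r = rng.normal(0.0, np.sqrt(comp.rater_var), size=k)
        e = rng.normal(0.0, np.sqrt(comp.residual_var), size=(n, k))
        y = mean + s[:, None] + r[None, :] + e
        frames.append(y)

    # built row-wise to keep ordering stable: subject-major, then feature, then slot
    rows = []
    for i in range(n):
        subj = f"S{i + 1:03d}"
        for f in range(n_features):
            feat = f"{feature_prefix}{f:0{width}d}"
            for j, (sc, pr, tp) in enumerate(cols):
                rows.append((subj, sc, pr, tp, feat, frames[f][i, j]))
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    table["value"] = table["value"].astype(float)
    return table


def calibrated_measurements(
    rng: np.random.Generator,
    n: int,
    k: int,
    icc: float,
    scale: float = 1.0,
    mean: float = 0.0,
    rater_sd: float = 0.0,
) -> np.ndarray:
    """An n x k matrix whose *sample* consistency ICC equals ``icc`` exactly.

    Draws the two-way model, then rescales the realized row-effect and
    residual subspaces so the sample mean squares hit the targets (the
    moment-matching idiom of ``MASS::mvrnorm(empirical=TRUE)``).  Used by the
    tiered fixtures, where classification recovery must be a construction
    property rather than a Monte-Carlo event.
    """
    if not (-1.0 / (k - 1) <= icc < 1.0):
        raise ValueError(f"icc must lie in [-1/(k-1), 1), got {icc}")
    ms_e = 1.0
    ms_r = ms_e * (1.0 + (k - 1) * icc) / (1.0 - icc)
    a = rng.normal(size=(n, k))
    grand = a.mean()
    row = a.mean(axis=1) - grand
    col = a.mean(axis=0) - grand
    resid = a - grand - row[:, None] - col[None, :]
    row *= np.sqrt(ms_r * (n - 1) / (k * np.sum(row**2)))
    resid *= np.sqrt(ms_e * (n - 1) * (k - 1) / np.sum(resid**2))
    offsets = rng.normal(0.0, rater_sd, size=k) if rater_sd > 0 else np.zeros(k)
    return mean + scale * (row[:, None] + resid) + offsets[None, :]


# ---------------------------------------------------------------------------
# phantom volume generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal model of the synthetic image-quality phantom.

    The region of interest is the largest fillable sphere (37 mm diameter)
    at a 4:1 target-to-background ratio.  ``noise_reference`` is the noise
    standard deviation at the reference exposure product
    ``reference_ma_mm`` (mA x slice thickness); other protocols scale as
    ``1/sqrt(mA x thickness)``.
    """

    interior_length: float = 64.0
    sphere_diameter: float = 37.0
    target_background_ratio: float = 4.0
    background_level: float = 100.0
    noise_reference: float = 10.0
    reference_ma_mm: float = 1500.0

    def noise_std(self, protocol: Protocol) -> float:
        if self.noise_reference == 0:
            return 0.0
        product = protocol.tube_current_ma * protocol.slice_thickness_mm
        return self.noise_reference * np.sqrt(self.reference_ma_mm / product)


def generate_phantom_volume(
    spec: PhantomSpec,
    protocol: Protocol,
    timepoint: int | str,
    seed: int,
    subsample: int = 3,
) -> tuple[ImageVolume, ImageVolume]:
    """Render one phantom scan: (intensity volume, exact sphere mask).

    The sphere is centered in the field of view.  Voxel membership is
    averaged over ``subsample``^3 sub-voxel points, giving deterministic,
    resolution-aware partial-volume edges.  Only the additive noise
    realization differs between timepoints (via the seed).
    """
    spacing = protocol.voxel_spacing_zyx()
    if any(s <= 0 for s in spacing):
        raise ValueError(f"protocol voxel sizes must be > 0, got {spacing}")
    if spec.sphere_diameter > spec.interior_length:
        raise ValueError(
            f"sphere diameter {spec.sphere_diameter} mm does not fit in the "
            f"{spec.interior_length} mm field of view"
        )
    shape = tuple(int(np.ceil(spec.interior_length / s)) for s in spacing)
    radius = spec.sphere_diameter / 2.0
    center = [(sh - 1) * sp / 2.0 for sh, sp in zip(shape, spacing)]

    # squared distance of every voxel center to the sphere center, per axis
    axes = [
        (np.arange(sh) * sp - c) for sh, sp, c in zip(shape, spacing, center)
    ]
    d2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    mask = (d2 <= radius**2).astype(np.uint8)

    # partial-volume fraction from supersampled sphere membership
    frac = np.zeros(shape)
    offsets = (np.arange(subsample) - (subsample - 1) / 2.0) / subsample
    sub_axes = [
        (ax[:, None] + off[None, :] * sp).ravel()
        for ax, sp, off in zip(axes, spacing, [offsets] * 3)
    ]
    sd2 = (
        sub_axes[0][:, None, None] ** 2
        + sub_axes[1][None, :, None] ** 2
        + sub_axes[2][None, None, :] ** 2
    )
    inside = (sd2 <= radius**2).reshape(
        shape[0], subsample, shape[1], subsample, shape[2], subsample
    )
    frac = inside.mean(axis=(1, 3, 5))

    bg = spec.background_level
    values = bg + (spec.target_background_ratio - 1.0) * bg * frac
    std = spec.noise_std(protocol)
    if std > 0:
        tp_key = int(timepoint) if str(timepoint).isdigit() else abs(hash(str(timepoint))) % 2**16
        rng = _rng(seed, tp_key)
        values = values + rng.normal(0.0, std, size=shape)

    vol = ImageVolume(values, spacing)
    msk = ImageVolume(mask, spacing)
    return vol, msk


# ---------------------------------------------------------------------------
# study fixtures
# ---------------------------------------------------------------------------


@dataclass
class PhantomSlot:
    scanner: str
    protocol: Protocol
    timepoint: int
    volume: ImageVolume
    mask: ImageVolume
    subject: str = "phantom"


@dataclass
class ClinicalFixture:
    """Designed 104-subject x 3-protocol table with known truth.

    ``truth`` has one row per feature: ``true_icc`` (exact sample ICC for
    tier features), ``kind`` in {tier, volume_proxy} and ``designed_class``.
    ``volumes`` is the per-subject gross tumor volume covariate in cm^3.
    """

    table: pd.DataFrame
    volumes: pd.Series
    truth: pd.DataFrame


@dataclass
class RiderFixture:
    table: pd.DataFrame
    truth: pd.DataFrame


def make_phantom_fixture(
    seed: int,
    spec: PhantomSpec | None = None,
    layout: StudyLayout | None = None,
    retest_identical: bool = False,
) -> list[PhantomSlot]:
    """All 36 labeled phantom scan slots (6 protocols x 3 scanners x 2).

    ``retest_identical=True`` reuses the test-scan noise stream for the
    retest, producing byte-identical pairs (the zero-variation control).
    """
    spec = spec or PhantomSpec()
    layout = layout or phantom_layout()
    slots = []
    for si, scanner in enumerate(layout.scanners):
        protocols = _phantom_protocols(scanner)
        for pi, proto in enumerate(protocols):
            for tp in range(1, layout.timepoints + 1):
                tp_eff = 1 if retest_identical else tp
                slot_seed = np.random.SeedSequence(
                    int(seed), spawn_key=(si, pi)
                ).generate_state(1)[0] % (2**31)
                vol, msk = generate_phantom_volume(spec, proto, tp_eff, slot_seed)
                slots.append(PhantomSlot(scanner, proto, tp, vol, msk))
    return slots


def make_sphere_cohort_fixture(
    seed: int,
    subjects: int = 8,
    diameter_range: tuple[float, float] = (24.0, 37.0),
    protocol: Protocol | None = None,
    noise_reference: float = 10.0,
    timepoints: int = 2,
) -> list[PhantomSlot]:
    """A test-retest cohort of sphere phantoms with varying diameters.

    Emulates a population with genuine between-subject variation (sphere
    size stands in for tumor size), so the subject variance of the ICC is
    independent of the image noise level.  On the single-sphere 36-slot
    fixture, the between-row variance is protocol-driven and itself grows
    with noise (the noise level is a protocol signature), which inverts
    the intuitive noise -> repeatability relationship; this cohort is the
    clean design for studying how noise degrades test-retest agreement.
    """
    protocol = protocol or Protocol("P1", 100, 2.0, 0.86)
    diameters = np.linspace(*diameter_range, subjects)
    slots = []
    for si, diam in enumerate(diameters):
        spec = PhantomSpec(noise_reference=noise_reference, sphere_diameter=float(diam))
        for tp in range(1, timepoints + 1):
            slot_seed = np.random.SeedSequence(int(seed), spawn_key=(si,)).generate_state(1)[0] % (
                2**31
            )
            vol, msk = generate_phantom_volume(spec, protocol, tp, slot_seed)
            slots.append(
                PhantomSlot(
                    "scanner1", protocol, tp, vol, msk, subject=f"S{si + 1:03d}"
                )
            )
    return slots


_TIER_CLASSES = {0.95: "good", 0.85: "moderate", 0.5: "poor"}


def _tiered_table(
    layout: StudyLayout,
    seed: int,
    tiers: dict[float, int],
    n_proxies: int = 0,
    volumes: pd.Series | None = None,
    proxy_power: float = 1.5,
    proxy_noise_sd: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    cols = layout.columns
    n, k = layout.subjects, len(cols)
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    rows = []
    truth_rows = []
    fidx = 0
    for tier_icc, count in tiers.items():
        for _ in range(count):
            feat = f"f{fidx:03d}"
            rng = _rng(seed, fidx)
            y = calibrated_measurements(rng, n, k, tier_icc, rater_sd=0.5)
            for i, subj in enumerate(subjects):
                for j, (sc, pr, tp) in enumerate(cols):
                    rows.append((subj, sc, pr, tp, feat, y[i, j]))
            truth_rows.append((feat, tier_icc, "tier", _TIER_CLASSES.get(tier_icc, "")))
            fidx += 1
    if n_proxies:
        if volumes is None:
            raise ValueError("volume proxies require a volumes covariate")
        v = volumes.to_numpy()
        for p in range(n_proxies):
            feat = f"f{fidx:03d}"
            rng = _rng(seed, fidx)
            base = v**proxy_power
            for j, (sc, pr, tp) in enumerate(cols):
                noisy = base * (1.0 + rng.normal(0.0, proxy_noise_sd, size=n))
                for i, subj in enumerate(subjects):
                    rows.append((subj, sc, pr, tp, feat, noisy[i]))
            truth_rows.append((feat, 1.0, "volume_proxy", "good"))
            fidx += 1
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    truth = pd.DataFrame(
        truth_rows, columns=["feature", "true_icc", "kind", "designed_class"]
    ).set_index("feature")
    return table, truth


def _simulate_volumes(n: int, seed: int) -> pd.Series:
    """Per-subject GTV in cm^3: lognormal, median ~90, clipped to 14-486."""
    rng = _rng(seed, 777)
    v = np.exp(rng.normal(np.log(90.0), 0.55, size=n))
    v = np.clip(v, 14.0, 486.0)
    return pd.Series(v, index=[f"S{i + 1:03d}" for i in range(n)], name="gtv_cm3")


def make_clinical_fixture(
    seed: int,
    subjects: int = 104,
    n_tier_features: int = 54,
    proxy_fraction: float = 0.10,
    tiers: dict[float, int] | None = None,
) -> ClinicalFixture:
    """104 subjects x 3 clinical protocols with tiered ICCs and GTV proxies.

    Tier features split evenly across designed ICC {0.95, 0.85, 0.5}; a
    designated 10% of the roster are monotone functions of tumor volume
    (``a * volume^b`` plus 1% multiplicative noise), the known true
    positives of the collinearity filter.
    """
    layout = clinical_layout(subjects)
    volumes = _simulate_volumes(subjects, seed)
    if tiers is None:
        per_tier = n_tier_features // 3
        tiers = {0.95: per_tier, 0.85: per_tier, 0.5: n_tier_features - 2 * per_tier}
    else:
        n_tier_features = sum(tiers.values())
    n_proxies = max(1, round(proxy_fraction * n_tier_features / (1 - proxy_fraction)))
    table, truth = _tiered_table(layout, seed, tiers, n_proxies, volumes)
    return ClinicalFixture(table, volumes, truth)


def make_rider_fixture(
    seed: int,
    subjects: int = 32,
    n_features: int = 60,
    tiers: dict[float, int] | None = None,
) -> RiderFixture:
    """32-subject test-retest table with designed good/moderate/poor tiers."""
    layout = rider_layout(subjects)
    if tiers is None:
        per = n_features // 3
        tiers = {0.95: per, 0.85: per, 0.5: n_features - 2 * per}
    table, truth = _tiered_table(layout, seed, tiers)
    return RiderFixture(table, truth)


def make_study_fixture(preset: str, seed: int, **kwargs):
    """Dispatch to one of the three study presets.

    ``phantom`` -> 36 labeled (volume, mask) slots; ``clinical`` -> a
    :class:`ClinicalFixture`; ``rider`` -> a :class:`RiderFixture`.
    """
    presets = {
        "phantom": make_phantom_fixture,
        "clinical": make_clinical_fixture,
        "rider": make_rider_fixture,
        "sphere_cohort": make_sphere_cohort_fixture,
    }
    if preset not in presets:
        raise ValueError(
            f"unknown preset {preset!r}; valid presets: {sorted(presets)}"
        )
    return presets[preset](seed, **kwargs)
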