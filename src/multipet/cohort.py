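"""Synthetic multi-tracer cohort generator.

Produces subject-level regional measures with the group effect structure the
downstream analysis assumes: amyloid (PIB) pons-ratios highest in sporadic AD
and amyloid-positive MCI, intermediate in presymptomatic mutation carriers and
low in non-carriers and amyloid-negative MCI; glucose metabolism (FDG) lowest
in symptomatic carriers and sporadic AD; and MAO-B availability (DED trapping
rate k3) highest in presymptomatic carriers. DED is generated as regional
time-activity curves through the forward compartment model so the kinetic
quantifier is exercised end to end; PIB and FDG are generated directly as
log-normally varying pons ratios.

Between-subject variation is log-normal (positivity preserved) and expected
years to onset (EYO) drives a mild monotone ramp for mutation carriers:
amyloid up and metabolism down as onset approaches, astrocytosis highest well
before onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import protocol
from .patlak import ded_slope_pipeline
from .roi import build_feature_table
from .tac import (
    FrameSchedule,
    InputFunction,
    KineticParams,
    TimeActivityCurve,
    add_noise,
    default_grid_min,
    sample_frames,
    tissue_tac_multi,
)

__all__ = [
    "SubjectSpec",
    "EffectProfile",
    "Cohort",
    "default_subject_specs",
    "simulate_cohort",
    "cohort_feature_table",
    "make_toy_atlas",
    "render_toy_volumes",
]

_SUBCORTICAL = {
    "caudate_nucleus",
    "putamen",
    "globus_pallidus",
    "nucleus_accumbens",
    "thalamus",
    "midbrain",
    "hippocampus",
    "amygdala",
    "parahippocampal_gyrus",
}
_CEREBELLAR = {"cerebellar_cortex", "cerebellar_vermis"}

#: Table-derived age distributions (mean, SD) per group, years.
AGE_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "sAD": (64.1, 6.1),
    "MCI_PIB+": (61.9, 6.8),
    "MCI_PIB-": (64.3, 6.7),
    "non_carrier": (54.3, 12.9),
    "presymptomatic_carrier": (43.5, 9.3),
    "symptomatic_carrier": (58.7, 5.0),
}

#: EYO (expected years to onset, negative = before) distributions for carriers.
EYO_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "presymptomatic_carrier": (-11.8, 8.1),
    "symptomatic_carrier": (1.9, 2.6),
}

_CARRIER_GROUPS = set(EYO_DISTRIBUTIONS)


@dataclass(frozen=True)
class SubjectSpec:
    id: str
    group: str
    age: float
    eyo: float | None = None  # carriers only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in protocol.GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if (self.eyo is not None) != (self.group in _CARRIER_GROUPS):
            raise ValueError("eyo must be set for carriers and only for carriers")


def _default_pib_baseline() -> dict[str, float]:
    base = {}
    for r in protocol.ATLAS_REGIONS:
        if r in _CEREBELLAR:
            base[r] = 1.00
        elif r in _SUBCORTICAL:
            base[r] = 1.10
        else:
            base[r] = 1.05
    return base


def _default_fdg_baseline() -> dict[str, float]:
    base = {}
    for r in protocol.ATLAS_REGIONS:
        if r in _CEREBELLAR:
            base[r] = 1.35
        elif r in _SUBCORTICAL:
            base[r] = 1.30
        else:
            base[r] = 1.50
    return base


def _default_ded_k3() -> dict[str, float]:
    # MAO-B availability is higher subcortically; cerebellum is near the
    # reference level (it accumulates only weakly, hence the k3 correction).
    base = {}
    for r in protocol.ATLAS_REGIONS:
        if r in _CEREBELLAR:
            base[r] = 0.012
        elif r in _SUBCORTICAL:
            base[r] = 0.045
        else:
            base[r] = 0.035
    return base


@dataclass(frozen=True)
class EffectProfile:
    """Group/region effect multipliers and variability for the simulator.

    Multipliers encode the qualitative group orderings the analysis is built
    to detect; absolute patient values are not targeted. The amyloid effect is
    absent in the hippocampus and cerebellum; metabolic and astrocytosis
    effects spare the cerebellum (reference territory).
    """

    pib_group: dict[str, float] = field(
        default_factory=lambda: {
            "sAD": 1.90,
            "MCI_PIB+": 1.85,
            "MCI_PIB-": 0.96,
            "non_carrier": 1.00,
            "presymptomatic_carrier": 1.40,
            "symptomatic_carrier": 2.10,
        }
    )
    fdg_group: dict[str, float] = field(
        default_factory=lambda: {
            "sAD": 0.80,
            "MCI_PIB+": 0.84,
            "MCI_PIB-": 0.97,
            "non_carrier": 1.00,
            "presymptomatic_carrier": 0.93,
            "symptomatic_carrier": 0.75,
        }
    )
    ded_group: dict[str, float] = field(
        default_factory=lambda: {
            "sAD": 0.88,
            "MCI_PIB+": 1.30,
            "MCI_PIB-": 0.82,
            "non_carrier": 1.00,
            "presymptomatic_carrier": 1.55,
            "symptomatic_carrier": 1.15,
        }
    )
    pib_baseline: dict[str, float] = field(default_factory=_default_pib_baseline)
    fdg_baseline: dict[str, float] = field(default_factory=_default_fdg_baseline)
    ded_k3_baseline: dict[str, float] = field(default_factory=_default_ded_k3)
    no_pib_effect_regions: frozenset = frozenset({"hippocampus"} | _CEREBELLAR)
    no_fdg_effect_regions: frozenset = frozenset(_CEREBELLAR)
    no_ded_effect_regions: frozenset = frozenset(_CEREBELLAR)
    between_subject_cv: float = 0.08
    noise_cv: float = 0.05
    eyo_ramp_amplitude: float = 0.10  # mild carrier modulation around group mean
    eyo_ramp_span_years: float = 25.0

    def __post_init__(self) -> None:
        for name in ("pib_group", "fdg_group", "ded_group"):
            mults = getattr(self, name)
            if set(mults) != set(protocol.GROUPS):
                raise ValueError(f"{name} must define every group")
            if any(m <= 0 for m in mults.values()):
                raise ValueError(f"{name} multipliers must be > 0")

    def eyo_ramp(self, eyo: float) -> float:
        """0 far before onset, 1 at/after onset, linear in between."""
        return float(np.clip((eyo + self.eyo_ramp_span_years) / self.eyo_ramp_span_years, 0.0, 1.0))

    def severity_score(self, group: str) -> float:
        """Encoded amyloid-up/metabolism-down severity (component-1 axis)."""
        return self.pib_group[group] - self.fdg_group[group]

    def ded_score(self, group: str) -> float:
        """Encoded astrocytosis effect (component-2 axis)."""
        return self.ded_group[group]


@dataclass
class Cohort:
    subjects: list[SubjectSpec]
    pib_ratios: pd.DataFrame  # subjects × regions, pons-normalised
    fdg_ratios: pd.DataFrame
    ded_tacs: dict[str, dict[str, TimeActivityCurve]]  # subject → region → TAC
    ded_reference: dict[str, TimeActivityCurve]  # subject → cerebellar reference

    @property
    def groups(self) -> dict[str, str]:
        return {s.id: s.group for s in self.subjects}

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [s.id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "eyo": [s.eyo for s in self.subjects],
            }
        ).set_index("subject")


def default_subject_specs(
    sizes: dict[str, int] | None = None, master_seed: int = 0
) -> list[SubjectSpec]:
    """Build subject specs with study-default group sizes and demographics."""
    sizes = dict(protocol.GROUP_SIZES) if sizes is None else sizes
    unknown = set(sizes) - set(protocol.GROUPS)
    if unknown:
        raise ValueError(f"unknown group(s) {sorted(unknown)}")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(sum(sizes.values()))
    specs = []
    i = 0
    for group in protocol.GROUPS:
        n = sizes.get(group, 0)
        if n < 0:
            raise ValueError("group sizes must be >= 0")
        mu, sd = AGE_DISTRIBUTIONS[group]
        for k in range(n):
            child = children[i]
            rng = np.random.default_rng(child)
            age = float(rng.normal(mu, sd))
            eyo = None
            if group in _CARRIER_GROUPS:
                emu, esd = EYO_DISTRIBUTIONS[group]
                eyo = float(rng.normal(emu, esd))
            specs.append(
                SubjectSpec(
                    id=f"{group}_{k + 1:03d}",
                    group=group,
                    age=age,
                    eyo=eyo,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
            )
            i += 1
    return specs


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def simulate_cohort(
    profile: EffectProfile | None = None,
    sizes: dict[str, int] | None = None,
    master_seed: int = 0,
    schedule: FrameSchedule | None = None,
    input_fn: InputFunction | None = None,
    subjects: list[SubjectSpec] | None = None,
) -> Cohort:
    """Generate a full synthetic cohort, deterministic under ``master_seed``.

    DED regional TACs come from the forward 2TCM with group/region-specific
    trapping; PIB and FDG regional pons-ratios are drawn log-normally around
    group/region means. Per-subject randomness is split from the master seed.
    """
    profile = profile or EffectProfile()
    schedule = schedule or protocol.FRAME_SCHEDULES["DED"]
    input_fn = input_fn or InputFunction()
    if subjects is None:
        subjects = default_subject_specs(sizes, master_seed)
    regions = list(protocol.ATLAS_REGIONS)
    grid = default_grid_min()
    pib_rows, fdg_rows = {}, {}
    ded_tacs: dict[str, dict[str, TimeActivityCurve]] = {}
    ded_ref: dict[str, TimeActivityCurve] = {}
    for spec in subjects:
        rng = np.random.default_rng(spec.seed)
        pib_mult = profile.pib_group[spec.group]
        fdg_mult = profile.fdg_group[spec.group]
        ded_mult = profile.ded_group[spec.group]
        if spec.eyo is not None and profile.eyo_ramp_amplitude > 0:
            ramp = profile.eyo_ramp(spec.eyo)
            mod = profile.eyo_ramp_amplitude * (ramp - 0.5)
            pib_mult *= 1.0 + mod  # amyloid rises toward onset
            fdg_mult *= 1.0 - mod  # metabolism falls toward onset
            ded_mult *= 1.0 - mod  # astrocytosis declines toward/after onset
        bs = profile.between_subject_cv
        subject_pib = _lognormal_factor(rng, bs)
        subject_fdg = _lognormal_factor(rng, bs)
        subject_ded = _lognormal_factor(rng, bs)
        pib_row, fdg_row = {}, {}
        k3_values = np.empty(len(regions))
        for j, r in enumerate(regions):
            pm = 1.0 if r in profile.no_pib_effect_regions else pib_mult
            fm = 1.0 if r in profile.no_fdg_effect_regions else fdg_mult
            dm = 1.0 if r in profile.no_ded_effect_regions else ded_mult
            pib_row[r] = (
                profile.pib_baseline[r]
                * pm
                * subject_pib
                * _lognormal_factor(rng, bs / 2)
                * _lognormal_factor(rng, profile.noise_cv)
            )
            fdg_row[r] = (
                profile.fdg_baseline[r]
                * fm
                * subject_fdg
                * _lognormal_factor(rng, bs / 2)
                * _lognormal_factor(rng, profile.noise_cv)
            )
            k3_values[j] = profile.ded_k3_baseline[r] * dm * subject_ded * _lognormal_factor(
                rng, bs / 2
            )
        pib_rows[spec.id] = pib_row
        fdg_rows[spec.id] = fdg_row
        # DED forward model: shared delivery/efflux, region-specific trapping
        K1 = 0.30 * _lognormal_factor(rng, bs / 2)
        k2 = 0.20
        curves = tissue_tac_multi(K1, k2, k3_values, input_fn, grid)
        frame_vals = sample_frames(grid, curves, schedule)
        subject_tacs = {}
        for j, r in enumerate(regions):
            tac = TimeActivityCurve(schedule, frame_vals[j])
            subject_tacs[r] = add_noise(tac, profile.noise_cv, rng)
        ded_tacs[spec.id] = subject_tacs
        # cerebellar gray-matter reference: weak trapping at the corrected rate
        ref_curve = tissue_tac_multi(K1, k2, np.array([0.01]), input_fn, grid)
        ref_vals = sample_frames(grid, ref_curve, schedule)[0]
        ded_ref[spec.id] = add_noise(
            TimeActivityCurve(schedule, ref_vals), profile.noise_cv, rng
        )
    index = [s.id for s in subjects]
    return Cohort(
        subjects=list(subjects),
        pib_ratios=pd.DataFrame.from_dict(pib_rows, orient="index").loc[index, regions],
        fdg_ratios=pd.DataFrame.from_dict(fdg_rows, orient="index").loc[index, regions],
        ded_tacs=ded_tacs,
        ded_reference=ded_ref,
    )


def cohort_feature_table(
    cohort: Cohort,
    k3_ref: float = protocol.K3_REF_PER_MIN,
    window: tuple[float, float] = protocol.PATLAK_WINDOW_MIN,
) -> pd.DataFrame:
    """Quantify DED slopes per subject/region and assemble the feature table."""
    measures: dict[str, dict[str, dict[str, float]]] = {}
    for spec in cohort.subjects:
        sid = spec.id
        ref = cohort.ded_reference[sid]
        slopes = {
            region: ded_slope_pipeline(tac, ref, k3_ref=k3_ref, window=window).slope
            for region, tac in cohort.ded_tacs[sid].items()
        }
        measures[sid] = {
            "pib": cohort.pib_ratios.loc[sid].to_dict(),
            "fdg": cohort.fdg_ratios.loc[sid].to_dict(),
            "ded": slopes,
        }
    return build_feature_table(measures, cohort.groups)


def make_toy_atlas(shape: tuple[int, int, int] = (16, 16, 16)):
    """Deterministic toy label atlas + gray-matter map for voxel-level tests.

    The interior of the volume is split into contiguous chunks, one per atlas
    region plus the pons reference; interior voxels get gray-matter
    probability 0.9, the one-voxel border 0.1.
    """
    from .roi import GrayMatterMask, LabelAtlas

    labels = np.zeros(shape, dtype=np.int32)
    gm = np.full(shape, 0.1)
    interior = np.zeros(shape, dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    gm[interior] = 0.9
    idx = np.flatnonzero(interior.ravel())
    all_labels = sorted(protocol.ATLAS_LABELS)
    chunks = np.array_split(idx, len(all_labels))
    flat = labels.ravel()
    for label, chunk in zip(all_labels, chunks):
        flat[chunk] = label
    return LabelAtlas(labels, dict(protocol.ATLAS_LABELS)), GrayMatterMask(gm)


def render_toy_volumes(
    values: dict[str, float | np.ndarray],
    atlas,
    gm,
    noise_sd: float = 0.0,
    seed=0,
) -> np.ndarray:
    """Paint per-region values (scalars → 3-D, per-frame arrays → 4-D) into
    the atlas voxels, plus optional additive Gaussian voxel noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    name_to_label = {v: k for k, v in atlas.names.items()}
    first = next(iter(values.values()))
    if np.ndim(first) == 0:
        out = np.zeros(atlas.labels.shape)
        for region, value in values.items():
            out[atlas.labels == name_to_label[region]] = value
        if noise_sd > 0:
            out = out + rng.normal(0.0, noise_sd, size=out.shape)
        return out
    n_frames = len(first)
    out = np.zeros((n_frames,) + atlas.labels.shape)
    for region, series in values.items():
        mask = atlas.labels == name_to_label[region]
        out[:, mask] = np.asarray(series, dtype=float)[:, None]
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return out
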