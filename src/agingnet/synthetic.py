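"""Synthetic aging-cohort generator with planted effects.

Generates complete cohorts — demographics, per-lobe cortical thickness,
BOLD-like ROI time series with nuisance contamination, and fiber tallies —
whose lobe-pair connectivity strengths carry known (planted) standardized age
effects and mediation structure, so the whole pipeline
(preprocess -> netbuild -> metrics -> stats) can be validated end to end.

Planting convention
-------------------
Effects are planted on the standardized scale.  For a lobe pair with planted
coefficients (beta_age, beta_age2, beta_sex), the latent standardized
strength of subject i is

    s_i = beta_age * z(age)_i + beta_age2 * z(age^2)_i + beta_sex * sex_i
          + sigma * eps_i

with sigma chosen so the latent values have unit variance (matching the
design matrix convention of the stats module, including the collinear raw
age^2 term), unless an explicit ``noise_sd`` overrides it.  The latent value
is then mapped affinely onto the modality's raw scale
(``base + scale_sd * s``).  Mediation pathways replace the independent draws
of the named mediator/outcome pairs with

    M = a * z(age) + e_M          (unit variance)
    Y = c' * z(age) + b * M + e_Y (unit variance)

so that recovered path coefficients can be compared to (a, b, c') directly.

Demographics default to the stratified design of the emulated study: decade
strata of 32/24/27/42/48 subjects (total 173) with per-decade mean ages
25.6/34/44.8/54.8/67.4 years and female fractions 56/50/63/60/71 %.  Time
series default to T=156 timepoints at TR=2.3 s (a 6-minute acquisition).

All randomness flows through per-subject streams keyed by (seed, subject
index), so a cohort is reproducible under subject subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import Atlas, Lobe, default_atlas
from .netbuild import FiberRecord, FiberTally, Modality
from .preprocess import NuisanceSet, TimeSeriesPanel

# Stratified design of the emulated cohort: decade bin edges, counts,
# mean (sd) ages, and female percentages.
STRATA_BOUNDS = ((21, 29), (30, 39), (40, 49), (50, 59), (60, 80))
STRATA_COUNTS = (32, 24, 27, 42, 48)
STRATA_AGE_MEAN = (25.6, 34.0, 44.8, 54.8, 67.4)
STRATA_AGE_SD = (2.22, 2.54, 2.68, 3.11, 4.83)
STRATA_FEMALE_PCT = (56, 50, 63, 60, 71)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level design: who is scanned and how."""

    n_subjects: int = 173
    age_model: str = "stratified"  # "stratified" or "uniform"
    age_range: tuple[float, float] = (21.0, 80.0)
    female_fraction: float = 0.61
    t_points: int = 156
    tr_seconds: float = 2.3
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.t_points < 32:
            raise ValueError("need at least 32 timepoints")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in [0, 1]")
        if self.age_model not in ("stratified", "uniform"):
            raise ValueError(f"unknown age_model {self.age_model!r}")


@dataclass(frozen=True)
class PlantedEffect:
    """Standardized-scale age/sex effect for one lobe pair in one modality."""

    modality: Modality
    lobe_a: Lobe
    lobe_b: Lobe
    beta_age: float = 0.0
    beta_age2: float = 0.0
    beta_sex: float = 0.0
    noise_sd: float | None = None  # None -> complete latent variance to 1
    # An inverted-U (nonzero beta_age2) needs a compensating linear term
    # because raw age and age^2 are nearly collinear: with this flag the
    # linear coefficient is augmented by -corr(z_age, z_age2) * beta_age2,
    # the minimum-variance configuration, leaving beta_age2 as specified.
    complement_linear: bool = False

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.modality.value, self.lobe_a.value, self.lobe_b.value)


@dataclass(frozen=True)
class MediationSpec:
    """Planted age -> mediator -> outcome pathway on the standardized scale.

    ``mediator`` is either ("<modality>", lobe_a, lobe_b) naming a strength,
    or ("thickness", lobe) naming a per-lobe mean cortical thickness.
    """

    a: float
    b: float
    c_prime: float
    mediator: tuple
    outcome: tuple[str, Lobe, Lobe]


@dataclass(frozen=True)
class EffectSpec:
    """Everything planted into a synthetic cohort."""

    effects: tuple[PlantedEffect, ...] = ()
    mediations: tuple[MediationSpec, ...] = ()
    # raw-scale mapping of the standardized latent strengths; a planted
    # between-lobe correlation must stay below the within-lobe base for the
    # target matrix to remain (near) positive definite, and the
    # between-subject spread (scale) must dominate the sampling noise of a
    # T~156 correlation estimate or planted age effects would be strongly
    # attenuated by measurement error on their way through the pipeline
    functional_base: float = 0.2
    functional_scale: float = 0.2
    structural_base: float = 0.004
    structural_scale: float = 0.0008
    # unplanted network background
    functional_within_lobe: float = 0.65
    functional_between_lobe: float = 0.1
    structural_background: float = 0.003
    # thickness model: mm at age 21, decline per year, residual sd
    thickness_intercept_mm: float = 2.8
    thickness_slope_mm_per_year: float = 0.005
    thickness_noise_sd: float = 0.05
    thickness_scale: float = 0.15  # mm per latent sd for mediator thickness
    # tractography geometry
    voxel_count_range: tuple[int, int] = (100, 500)
    mm3_per_voxel: float = 27.0
    streamlines_per_voxel: int = 1000
    # BOLD signal model
    bold_baseline: float = 1000.0
    bold_sd: float = 2.0
    drift_sd: float = 4.0
    nuisance_load_sd: float = 1.0

    def __post_init__(self):
        for e in self.effects:
            if e.noise_sd is not None and e.noise_sd <= 0:
                raise ValueError("noise_sd must be positive when given")
        self._check_acyclic()

    def _check_acyclic(self):
        outs = {m.outcome for m in self.mediations}
        for m in self.mediations:
            if m.mediator == m.outcome:
                raise ValueError("mediator and outcome must be distinct")
            if m.mediator in outs:
                raise ValueError(
                    f"cyclic mediation spec: {m.mediator} is also a mediated outcome"
                )


def default_study_effects() -> EffectSpec:
    """Planted effects mirroring the qualitative pattern of the emulated study.

    Structural connectivity of the prefrontal cortex with the temporal and
    sensorimotor lobes increases linearly with age; prefrontal-parietal
    structural connectivity follows an inverted U (negative quadratic term);
    occipital connectivity with the lateral temporal and parietal lobes
    increases with age, and the occipital-lateral-temporal increase partially
    mediates the prefrontal-lateral-temporal one (a=0.42, b=0.40, c'=0.12,
    total = c' + a*b = 0.288).  One functional pair declines with age
    (prefrontal-parietal) and one increases (occipital-lateral temporal).
    Magnitudes are illustrative, chosen to match the signs and rough sizes of
    the emulated findings.
    """
    S, F = Modality.STRUCTURAL, Modality.FUNCTIONAL
    effects = (
        PlantedEffect(S, Lobe.PREFRONTAL, Lobe.MEDIAL_TEMPORAL, beta_age=0.28),
        PlantedEffect(S, Lobe.PREFRONTAL, Lobe.MOTOR_SENSORY, beta_age=0.23),
        PlantedEffect(S, Lobe.PREFRONTAL, Lobe.PARIETAL, beta_age2=-1.5, complement_linear=True),
        PlantedEffect(S, Lobe.OCCIPITAL, Lobe.PARIETAL, beta_age=0.21),
        PlantedEffect(F, Lobe.PREFRONTAL, Lobe.PARIETAL, beta_age=-0.2),
        PlantedEffect(F, Lobe.OCCIPITAL, Lobe.LATERAL_TEMPORAL, beta_age=0.16),
    )
    mediations = (
        MediationSpec(
            a=0.42,
            b=0.40,
            c_prime=0.12,
            mediator=("structural", Lobe.OCCIPITAL, Lobe.LATERAL_TEMPORAL),
            outcome=("structural", Lobe.PREFRONTAL, Lobe.LATERAL_TEMPORAL),
        ),
    )
    return EffectSpec(effects=effects, mediations=mediations)


# ---------------------------------------------------------------------------
# RNG plumbing


def _cohort_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))

def _subject_rng(seed: int, subject_index: int, stream: int) -> np.random.Generator:
    """Independent stream keyed by (seed, subject, purpose)."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(subject_index, stream))
    )


def _subject_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"s{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# demographics


def generate_demographics(spec: CohortSpec) -> pd.DataFrame:
    """Cohort table (subject_id, age, sex) with sex coded 0=male, 1=female.

    Stratified mode draws exactly the per-decade counts of the emulated
    design (total 173, overriding ``n_subjects``) from truncated normals
    matching the printed per-decade means and SDs, with the printed female
    percentages.  Uniform mode draws ``n_subjects`` ages uniformly over
    ``age_range``.
    """
    rng = _cohort_rng(spec.seed)
    if spec.age_model == "stratified":
        ages, sexes = [], []
        for (lo, hi), n, mu, sd, fpct in zip(
            STRATA_BOUNDS, STRATA_COUNTS, STRATA_AGE_MEAN, STRATA_AGE_SD, STRATA_FEMALE_PCT
        ):
            draws = []
            while len(draws) < n:
                x = rng.normal(mu, sd, size=n)
                draws.extend(x[(x >= lo) & (x <= hi)])
            ages.extend(draws[:n])
            n_female = int(round(n * fpct / 100.0))
            sex = np.array([1] * n_female + [0] * (n - n_female))
            rng.shuffle(sex)
            sexes.extend(sex.tolist())
        ages = np.array(ages)
        sexes = np.array(sexes)
    else:
        n = spec.n_subjects
        lo, hi = spec.age_range
        ages = rng.uniform(lo, hi, size=n)
        n_female = int(round(n * spec.female_fraction))
        sexes = np.array([1] * n_female + [0] * (n - n_female))
        rng.shuffle(sexes)
    return pd.DataFrame(
        {"subject_id": _subject_ids(len(ages)), "age": ages, "sex": sexes}
    )


# ---------------------------------------------------------------------------
# latent planted strengths


def _standardized_design(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    age = cohort["age"].to_numpy(float)
    z = (age - age.mean()) / age.std(ddof=1)
    a2 = age**2
    z2 = (a2 - a2.mean()) / a2.std(ddof=1)
    return {"age": z, "age2": z2, "sex": cohort["sex"].to_numpy(float)}


def _latent_strength(
    effect: PlantedEffect, design: Mapping[str, np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    beta_age = effect.beta_age
    if effect.complement_linear and effect.beta_age2 != 0.0:
        r = float(np.corrcoef(design["age"], design["age2"])[0, 1])
        beta_age = beta_age - r * effect.beta_age2
    det = (
        beta_age * design["age"]
        + effect.beta_age2 * design["age2"]
        + effect.beta_sex * design["sex"]
    )
    if effect.noise_sd is not None:
        sigma = effect.noise_sd
    else:
        var_det = det.var(ddof=1)
        if var_det >= 1.0:
            raise ValueError(
                f"planted effect {effect.key} has deterministic variance "
                f"{var_det:.3f} >= 1; cannot complete to unit variance"
            )
        sigma = float(np.sqrt(1.0 - var_det))
    return det + sigma * rng.standard_normal(det.size)


def plant_mediation(
    cohort: pd.DataFrame, effects: EffectSpec, seed: int
) -> dict[tuple, np.ndarray]:
    """Standardized latent values for every mediation pathway.

    Returns a mapping from the mediator/outcome keys of
    :class:`MediationSpec` to per-subject latent vectors with (approximately)
    unit variance, built by the path equations M = a*z(age) + e_M and
    Y = c'*z(age) + b*M + e_Y.
    """
    design = _standardized_design(cohort)
    z = design["age"]
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(999,)))
    out: dict[tuple, np.ndarray] = {}
    for m in effects.mediations:
        var_m = 1.0 - m.a**2
        if var_m <= 0:
            raise ValueError(f"|a| must be < 1, got {m.a}")
        med = m.a * z + np.sqrt(var_m) * rng.standard_normal(z.size)
        var_y = 1.0 - (m.c_prime**2 + m.b**2 + 2 * m.a * m.b * m.c_prime)
        if var_y <= 0:
            raise ValueError(
                f"mediation (a={m.a}, b={m.b}, c'={m.c_prime}) implies outcome "
                f"variance {1 - var_y:.3f} >= 1; cannot complete to unit variance"
            )
        y = m.c_prime * z + m.b * med + np.sqrt(var_y) * rng.standard_normal(z.size)
        out[_norm_key(m.mediator)] = med
        out[_norm_key(m.outcome)] = y
    return out


def _norm_key(key: tuple) -> tuple:
    if key[0] == "thickness":
        return ("thickness", Lobe(key[1]).value)
    return (Modality(key[0]).value, Lobe(key[1]).value, Lobe(key[2]).value)


def planted_strengths(
    cohort: pd.DataFrame, effects: EffectSpec, seed: int
) -> pd.DataFrame:
    """Latent standardized strengths for every planted pair and pathway.

    One column per planted key ``"<modality>:<lobe_a>:<lobe_b>"`` (or
    ``"thickness:<lobe>"``), mediation pathways overriding independent
    effect draws for the same pair.
    """
    design = _standardized_design(cohort)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(998,)))
    latents: dict[tuple, np.ndarray] = {}
    for e in effects.effects:
        latents[_norm_key(e.key)] = _latent_strength(e, design, rng)
    latents.update(plant_mediation(cohort, effects, seed))
    df = pd.DataFrame({":".join(k): v for k, v in latents.items()})
    df.insert(0, "subject_id", cohort["subject_id"].to_numpy())
    return df


def _latent_lookup(latent_df: pd.DataFrame) -> dict[tuple, np.ndarray]:
    return {
        tuple(c.split(":")): latent_df[c].to_numpy(float)
        for c in latent_df.columns
        if c != "subject_id"
    }


# ---------------------------------------------------------------------------
# thickness


def generate_thickness(
    cohort: pd.DataFrame,
    effects: EffectSpec,
    atlas: Atlas,
    seed: int,
    latent_df: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-lobe mean cortical thickness table (mm), thinning with age.

    thickness = intercept - slope * (age - 21) + noise, floored at 1.0 mm.
    A lobe named as a mediation mediator instead gets
    mean - thickness_scale * latent, tying it to the planted pathway.
    """
    lobes = sorted({r.lobe for r in atlas if r.lobe is not Lobe.OTHER}, key=lambda l: l.value)
    age = cohort["age"].to_numpy(float)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(997,)))
    mean_th = effects.thickness_intercept_mm - effects.thickness_slope_mm_per_year * (
        age.mean() - 21.0
    )
    if mean_th <= 0:
        raise ValueError("thickness spec implies non-positive mean thickness")
    latents = _latent_lookup(latent_df) if latent_df is not None else {}
    out = {"subject_id": cohort["subject_id"].to_numpy()}
    for lobe in lobes:
        key = ("thickness", lobe.value)
        if key in latents:
            # mediator thickness: thinner for higher latent (atrophy direction)
            th = mean_th - effects.thickness_scale * latents[key]
        else:
            th = (
                effects.thickness_intercept_mm
                - effects.thickness_slope_mm_per_year * (age - 21.0)
                + effects.thickness_noise_sd * rng.standard_normal(age.size)
            )
        out[lobe.value] = np.maximum(th, 1.0)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# structural cohort


def _lobe_blocks(atlas: Atlas) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    blocks = {}
    named = [l for l in Lobe if l is not Lobe.OTHER]
    for la in named:
        ia = np.array(atlas.lobe_indices(la), dtype=int)
        for lb in named:
            ib = np.array(atlas.lobe_indices(lb), dtype=int)
            if ia.size and ib.size:
                blocks[(la.value, lb.value)] = (ia, ib)
    return blocks


def _set_pair_block(w: np.ndarray, ia: np.ndarray, ib: np.ndarray, value: float):
    w[np.ix_(ia, ib)] = value
    w[np.ix_(ib, ia)] = value


def _target_structural_weights(
    atlas: Atlas,
    effects: EffectSpec,
    latents: Mapping[tuple, np.ndarray],
    subj: int,
) -> np.ndarray:
    n = atlas.n_regions
    w = np.full((n, n), effects.structural_background)
    blocks = _lobe_blocks(atlas)
    for key, vals in latents.items():
        if key[0] != Modality.STRUCTURAL.value:
            continue
        ia, ib = blocks[(key[1], key[2])]
        raw = effects.structural_base + effects.structural_scale * vals[subj]
        _set_pair_block(w, ia, ib, max(raw, 0.0))
    np.fill_diagonal(w, 0.0)
    return w


def tally_from_weights(
    weights: np.ndarray,
    voxel_count: np.ndarray,
    volume_mm3: np.ndarray,
    streamlines_per_voxel: int,
    subject_id: str = "",
) -> FiberTally:
    """Invert the structural weight equation to integer fiber counts.

    Solves fcount_ij = round(w_ij * (C_i + V_j) / 2) for every ordered pair,
    so that the forward normalization reproduces ``weights`` within integer
    rounding.  Raises when a target weight would require more fibers than
    were sampled from the seed region (infeasible density).
    """
    c = voxel_count.astype(float) * streamlines_per_voxel
    denom = c[:, None] + volume_mm3[None, :]
    fcount = np.rint(weights * denom / 2.0).astype(np.int64)
    np.fill_diagonal(fcount, 0)
    if (fcount.sum(axis=1) > c).any():
        bad = np.flatnonzero(fcount.sum(axis=1) > c).tolist()
        raise ValueError(
            f"target weights imply more fibers than sampled for seed regions {bad}"
        )
    return FiberTally(
        fcount=fcount,
        voxel_count=voxel_count,
        volume_mm3=volume_mm3,
        streamlines_per_voxel=streamlines_per_voxel,
        subject_id=subject_id,
    )


def generate_structural(
    cohort: pd.DataFrame,
    effects: EffectSpec,
    atlas: Atlas,
    seed: int,
    latent_df: pd.DataFrame | None = None,
) -> list[FiberTally]:
    """Per-subject fiber tallies whose normalized weights match planted strengths."""
    if latent_df is None:
        latent_df = planted_strengths(cohort, effects, seed)
    latents = _latent_lookup(latent_df)
    tallies = []
    for i, sid in enumerate(cohort["subject_id"]):
        rng = _subject_rng(seed, i, stream=1)
        lo, hi = effects.voxel_count_range
        vox = rng.integers(lo, hi + 1, size=atlas.n_regions)
        vol = vox * effects.mm3_per_voxel
        w = _target_structural_weights(atlas, effects, latents, i)
        tallies.append(
            tally_from_weights(w, vox, vol, effects.streamlines_per_voxel, sid)
        )
    return tallies


def records_from_tally(
    tally: FiberTally,
    seed: int = 0,
    loop_fraction: float = 0.1,
    short_fraction: float = 0.2,
) -> list[FiberRecord]:
    """Raw streamline records reproducing ``tally`` after filtering.

    Emits one record of length ~ Uniform(10, 120) mm per tallied fiber, plus
    decoy records that the length/loop filter must remove: looping fibers
    (same seed and end region, any length) and short fibers (< 10 mm between
    distinct regions), in the given proportions of the clean record count.
    Only practical at toy scales; a full-size tally implies millions of rows.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(996,)))
    n = tally.n_regions
    records: list[FiberRecord] = []
    for i in range(n):
        for j in range(n):
            for _ in range(int(tally.fcount[i, j])):
                records.append(FiberRecord(i, j, float(rng.uniform(10.0, 120.0))))
    n_clean = len(records)
    for _ in range(int(round(loop_fraction * n_clean))):
        r = int(rng.integers(n))
        records.append(FiberRecord(r, r, float(rng.uniform(5.0, 120.0))))
    for _ in range(int(round(short_fraction * n_clean))):
        i, j = rng.choice(n, size=2, replace=False)
        records.append(FiberRecord(int(i), int(j), float(rng.uniform(5.0, 9.99))))
    order = rng.permutation(len(records))
    return [records[k] for k in order]


# ---------------------------------------------------------------------------
# functional cohort


def nearest_pd_correlation(
    c: np.ndarray, eig_floor: float = 1e-6, tol: float = 1e-8, max_iter: int = 200
) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix.

    Alternates eigenvalue clipping (floor ``eig_floor``) with unit-diagonal
    renormalization until both hold to ``tol``.
    """
    x = 0.5 * (c + c.T).astype(float)
    np.fill_diagonal(x, 1.0)
    for _ in range(max_iter):
        w, v = np.linalg.eigh(x)
        if w.min() >= eig_floor - tol and np.abs(np.diag(x) - 1.0).max() <= tol:
            return x
        w = np.clip(w, eig_floor, None)
        x = (v * w) @ v.T
        d = np.sqrt(np.diag(x))
        x = x / np.outer(d, d)
        x = 0.5 * (x + x.T)
        np.fill_diagonal(x, 1.0)
    raise ValueError("nearest-PD projection did not converge")


def _target_correlation(
    atlas: Atlas,
    effects: EffectSpec,
    latents: Mapping[tuple, np.ndarray],
    subj: int,
) -> tuple[np.ndarray, float]:
    """Subject target correlation matrix and the max planted-pair drift
    introduced by the PD projection (diagnostic)."""
    n = atlas.n_regions
    c = np.full((n, n), effects.functional_between_lobe)
    blocks = _lobe_blocks(atlas)
    for lobe in Lobe:
        idx = np.array(atlas.lobe_indices(lobe), dtype=int)
        if idx.size:
            c[np.ix_(idx, idx)] = effects.functional_within_lobe
    planted: list[tuple[np.ndarray, np.ndarray, float]] = []
    for key, vals in latents.items():
        if key[0] != Modality.FUNCTIONAL.value:
            continue
        ia, ib = blocks[(key[1], key[2])]
        # planted between-lobe correlations above the within-lobe base make
        # the target indefinite; clip just below it
        lim = effects.functional_within_lobe - 0.05
        raw = float(
            np.clip(
                effects.functional_base + effects.functional_scale * vals[subj],
                -lim,
                lim,
            )
        )
        _set_pair_block(c, ia, ib, raw)
        planted.append((ia, ib, raw))
    np.fill_diagonal(c, 1.0)
    proj = nearest_pd_correlation(c)
    drift = 0.0
    for ia, ib, raw in planted:
        drift = max(drift, abs(float(proj[np.ix_(ia, ib)].mean()) - raw))
    return proj, drift


@dataclass(frozen=True)
class FunctionalSubject:
    panel: TimeSeriesPanel
    nuisance: NuisanceSet
    target_correlation: np.ndarray
    pd_projection_drift: float


def generate_functional(
    cohort: pd.DataFrame,
    effects: EffectSpec,
    atlas: Atlas,
    spec: CohortSpec,
    latent_df: pd.DataFrame | None = None,
) -> list[FunctionalSubject]:
    """Per-subject BOLD-like panels with planted correlation structure.

    Each subject's clean signal is Gaussian with a block-structured target
    correlation matrix (within-lobe base, between-lobe base, planted pair
    blocks set to the subject's planted strength), projected to the nearest
    positive-definite correlation matrix.  On top of the clean signal sit a
    baseline offset, a per-region linear drift, and broadband nuisance
    signals (six motion-like regressors plus white-matter and ventricular
    means) with random per-region loadings; the nuisance series are also
    returned so preprocessing can remove them.
    """
    if latent_df is None:
        latent_df = planted_strengths(cohort, effects, spec.seed)
    latents = _latent_lookup(latent_df)
    subjects = []
    t, n = spec.t_points, atlas.n_regions
    for i, sid in enumerate(cohort["subject_id"]):
        rng = _subject_rng(spec.seed, i, stream=2)
        corr, drift_diag = _target_correlation(atlas, effects, latents, i)
        chol = np.linalg.cholesky(corr)
        clean = rng.standard_normal((t, n)) @ chol.T
        # nuisance: 6 motion-like + wm + csf, all broadband
        nuis = rng.standard_normal((t, 8))
        loads = rng.normal(0.0, effects.nuisance_load_sd, size=(8, n))
        loads[:6] *= 0.3  # motion parameters contaminate more weakly
        ramp = np.linspace(-0.5, 0.5, t)[:, None]
        drift_amp = rng.normal(0.0, effects.drift_sd, size=n)
        data = (
            effects.bold_baseline
            + effects.bold_sd * clean
            + nuis @ loads
            + ramp * drift_amp[None, :]
        )
        names = tuple(f"motion{k}" for k in range(1, 7)) + ("wm", "csf")
        subjects.append(
            FunctionalSubject(
                panel=TimeSeriesPanel(data, spec.tr_seconds, sid),
                nuisance=NuisanceSet(nuis, sid, names),
                target_correlation=corr,
                pd_projection_drift=drift_diag,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# whole cohorts


@dataclass
class SyntheticCohort:
    """A fully generated cohort, ready to feed the pipeline."""

    spec: CohortSpec
    effects: EffectSpec
    atlas: Atlas
    demographics: pd.DataFrame
    latent: pd.DataFrame
    thickness: pd.DataFrame
    tallies: list[FiberTally]
    functional: list[FunctionalSubject] | None

    @property
    def n_subjects(self) -> int:
        return len(self.demographics)


def generate_cohort(
    spec: CohortSpec,
    effects: EffectSpec | None = None,
    atlas: Atlas | None = None,
    include_functional: bool = True,
) -> SyntheticCohort:
    """Generate demographics, thickness, tallies and (optionally) time series."""
    effects = default_study_effects() if effects is None else effects
    atlas = default_atlas() if atlas is None else atlas
    demo = generate_demographics(spec)
    latent = planted_strengths(demo, effects, spec.seed)
    thickness = generate_thickness(demo, effects, atlas, spec.seed, latent)
    tallies = generate_structural(demo, effects, atlas, spec.seed, latent)
    functional = (
        generate_functional(demo, effects, atlas, spec, latent)
        if include_functional
        else None
    )
    return SyntheticCohort(
        spec=spec,
        effects=effects,
        atlas=atlas,
        demographics=demo,
        latent=latent,
        thickness=thickness,
        tallies=tallies,
        functional=functional,
    )
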