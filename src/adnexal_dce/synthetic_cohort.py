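"""Synthetic cohort and phantom generation with known kinetic ground truth.

No per-lesion data are publicly available for the adnexal-mass study this
package models, so validation runs on a synthetic cohort that reproduces the
study's statistical structure: 49 lesions in 43 patients (six patients with
bilateral disease), class counts 27 benign / 3 borderline / 19 malignant,
and per-class kinetic parameter distributions anchored to the published
group means and standard deviations.  Each lesion gets ground-truth extended
Tofts parameters drawn from its class distribution, a signal-time curve
simulated through the forward model and the population AIF, and Gaussian
noise scaled to the peak signal.  Measured-looking arterial curves for AIF
calibration and small 4-D phantom volumes for voxelwise-map testing are
generated the same way.

Semi-quantitative group differences are not drawn independently: they are
induced by the kinetic ground truth through the forward model plus a global
signal gain, so the descriptor and kinetic stages of the pipeline always see
internally consistent curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from adnexal_dce.aif import (
    AIFModel,
    ConcentrationCurve,
    blood_to_plasma,
    population_blood_curve,
    weinmann_aif,
)
from adnexal_dce.pk_model import PKParams, forward_extended_tofts
from adnexal_dce.protocol import DEFAULT_PROTOCOL, AcquisitionProtocol
from adnexal_dce.semiquant import EnhancementCurve

__all__ = [
    "CohortSpec",
    "LesionRecord",
    "CohortDataset",
    "sample_lesion_params",
    "simulate_lesion_curve",
    "simulate_measured_aifs",
    "generate_cohort",
    "generate_phantom_volume",
    "enhancement_gain",
    "DEFAULT_CLASS_PARAMS",
]

#: Per-class (mean, SD) anchors for the kinetic ground truth and patient
#: age, taken from the study's published group summaries.  Rates in 1/min,
#: vp as a fraction, age in years.
DEFAULT_CLASS_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "benign": {
        "ktrans": (0.03, 0.02),
        "kep": (1.89, 3.16),
        "vp": (0.10, 0.07),
        "age": (39.93, 8.38),
    },
    "borderline": {
        "ktrans": (0.03, 0.01),
        "kep": (3.67, 2.58),
        "vp": (0.25, 0.07),
        "age": (44.67, 16.29),
    },
    "malignant": {
        "ktrans": (0.05, 0.01),
        "kep": (5.38, 11.81),
        "vp": (0.22, 0.14),
        "age": (39.05, 12.51),
    },
}

#: Benign-group relative enhancement anchor (percent) used to set the
#: global signal gain: the benign class-mean kinetic template should
#: enhance by roughly this much over baseline.
BENIGN_SI_REL_ANCHOR = 97.36


@dataclass(frozen=True)
class CohortSpec:
    """Study-structure description for the synthetic cohort.

    ``noise_sd`` is the additive Gaussian noise SD as a fraction of the
    noiseless peak signal of each curve.  Each lesion curve stands for the
    ROI-mean signal of a multi-pixel hot-spot ROI, so the default (0.2% of
    peak) corresponds to voxel-level baseline SNR around 20 averaged over
    roughly 27 voxels.  ``distribution`` selects the sampling family for
    the kinetic parameters: zero-truncated normal (default) or a
    moment-matched lognormal.
    """

    n_benign: int = 27
    n_borderline: int = 3
    n_malignant: int = 19
    class_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            c: dict(p) for c, p in DEFAULT_CLASS_PARAMS.items()
        }
    )
    delta_frame_choices: tuple[int, ...] = (0, 1, 2)
    noise_sd: float = 0.002
    si0: float = 100.0
    n_bilateral: int = 6
    n_aif_curves: int = 10
    aif_noise_sd: float = 0.05
    distribution: str = "truncnorm"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_benign", "n_borderline", "n_malignant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_sd < 0 or self.aif_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.si0 <= 0:
            raise ValueError("si0 must be positive")
        if self.distribution not in ("truncnorm", "lognormal"):
            raise ValueError("distribution must be 'truncnorm' or 'lognormal'")
        for cls, params in self.class_params.items():
            for name, (_, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"{cls}/{name}: SD must be non-negative")

    @property
    def n_lesions(self) -> int:
        return self.n_benign + self.n_borderline + self.n_malignant


@dataclass(frozen=True)
class LesionRecord:
    """One synthetic lesion with its ground truth and simulated curve."""

    lesion_id: str
    patient_id: str
    laterality: str
    pathology: str
    age: float
    truth: PKParams
    curve: EnhancementCurve


@dataclass
class CohortDataset:
    """A generated cohort: lesion records plus shared calibration curves."""

    spec: CohortSpec
    protocol: AcquisitionProtocol
    aif: AIFModel
    gain: float
    records: list[LesionRecord]
    arterial_curves: list[ConcentrationCurve]

    def manifest(self) -> pd.DataFrame:
        """Ground-truth manifest, one row per lesion."""
        rows = []
        for r in self.records:
            rows.append({
                "lesion_id": r.lesion_id,
                "patient_id": r.patient_id,
                "laterality": r.laterality,
                "pathology": r.pathology,
                "age": r.age,
                "true_ktrans": r.truth.ktrans,
                "true_kep": r.truth.kep,
                "true_ve": r.truth.ve,
                "true_vp": r.truth.vp,
                "true_delta": r.truth.delta,
            })
        return pd.DataFrame(rows)

    def curves_frame(self) -> pd.DataFrame:
        """Long-format signal-time curves for every lesion."""
        frames = []
        for r in self.records:
            frames.append(pd.DataFrame({
                "lesion_id": r.lesion_id,
                "time_s": r.curve.times,
                "signal": r.curve.signal,
            }))
        return pd.concat(frames, ignore_index=True)

    def arterial_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.arterial_curves):
            rows.append(pd.DataFrame({
                "curve_id": f"AIF{i + 1:02d}",
                "time_s": c.times,
                "value": c.values,
            }))
        return pd.concat(rows, ignore_index=True)


def _truncated_draw(mean: float, sd: float, lo: float, hi: float,
                    rng: np.random.Generator) -> float:
    """One draw from N(mean, sd) truncated to [lo, hi]."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _lognormal_draw(mean: float, sd: float, rng: np.random.Generator) -> float:
    """One draw from a lognormal matched to the given mean and SD."""
    if sd == 0 or mean <= 0:
        return max(mean, 0.0)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def sample_lesion_params(
    pathology: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    protocol: AcquisitionProtocol = DEFAULT_PROTOCOL,
) -> PKParams:
    """Draw ground-truth kinetic parameters for one lesion of a given class.

    Rates are drawn from zero-truncated normals (or moment-matched
    lognormals), vp from a normal truncated to [0, 1]; the bolus lag is a
    uniform draw over a small set of whole-frame shifts.
    """
    if pathology not in spec.class_params:
        raise ValueError(f"unknown pathology class: {pathology!r}")
    params = spec.class_params[pathology]
    if spec.distribution == "lognormal":
        ktrans = _lognormal_draw(*params["ktrans"], rng)
        kep = _lognormal_draw(*params["kep"], rng)
        vp = min(_lognormal_draw(*params["vp"], rng), 1.0)
    else:
        ktrans = _truncated_draw(*params["ktrans"], 0.0, np.inf, rng)
        kep = _truncated_draw(*params["kep"], 0.0, np.inf, rng)
        vp = _truncated_draw(*params["vp"], 0.0, 1.0, rng)
    delta = float(rng.choice(spec.delta_frame_choices)) * protocol.frame_interval_s
    return PKParams(ktrans=ktrans, kep=kep, vp=vp, delta=delta)


def enhancement_gain(
    aif: AIFModel | None = None,
    protocol: AcquisitionProtocol = DEFAULT_PROTOCOL,
    class_params: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> float:
    """Global signal gain mapping tissue concentration to relative
    enhancement, SI(t) = SI0 (1 + gain * Ct(t)).

    The gain collapses relaxivity and T1 weighting into one constant, chosen
    so the benign class-mean kinetic template peaks at the benign-group
    relative-enhancement anchor.  With the same constant applied to the
    simulated arterial curves, AIF calibration recovers it and fitted
    parameters come out on the true scale.
    """
    if aif is None:
        aif = weinmann_aif(dose=protocol.dose_mmol_per_kg,
                           onset_time=protocol.injection_time_s)
    params = (class_params or DEFAULT_CLASS_PARAMS)["benign"]
    template = PKParams(ktrans=params["ktrans"][0], kep=params["kep"][0],
                        vp=params["vp"][0], delta=0.0)
    times = protocol.times()
    cp = blood_to_plasma(population_blood_curve(aif, times), aif.hct)
    ct = forward_extended_tofts(template, cp, times)
    ct_max = float(ct.values.max())
    if ct_max <= 0:
        raise ValueError("benign template produces no enhancement")
    return BENIGN_SI_REL_ANCHOR / 100.0 / ct_max


def simulate_lesion_curve(
    truth: PKParams,
    aif: AIFModel,
    protocol: AcquisitionProtocol,
    noise_sd: float,
    rng: np.random.Generator,
    si0: float = 100.0,
    gain: float | None = None,
) -> EnhancementCurve:
    """Simulate a noisy signal-time curve for one lesion.

    The tissue concentration from the forward model is converted to signal
    with ``SI = si0 (1 + gain * Ct)`` and corrupted with additive Gaussian
    noise whose SD is ``noise_sd`` times the noiseless peak signal.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if gain is None:
        gain = enhancement_gain(aif, protocol)
    times = protocol.times()
    cp = blood_to_plasma(population_blood_curve(aif, times), aif.hct)
    ct = forward_extended_tofts(truth, cp, times)
    signal = si0 * (1.0 + gain * ct.values)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd * signal.max(), signal.shape)
    return EnhancementCurve(
        times=times, signal=signal,
        injection_time=protocol.injection_time_s,
        frame_interval=protocol.frame_interval_s,
    )


def simulate_measured_aifs(
    aif: AIFModel,
    protocol: AcquisitionProtocol,
    n_curves: int,
    noise_sd: float,
    rng: np.random.Generator,
    gain: float | None = None,
) -> list[ConcentrationCurve]:
    """Simulate per-patient arterial blood curves on the acquisition grid.

    Each curve is the population blood curve expressed in relative
    enhancement units (multiplied by the signal gain) with multiplicative
    Gaussian noise, mimicking an AIF read from iliac-artery voxels.
    """
    if n_curves < 1:
        raise ValueError("need at least one arterial curve")
    if gain is None:
        gain = enhancement_gain(aif, protocol)
    times = protocol.times()
    cb = population_blood_curve(aif, times).values * gain
    curves = []
    for _ in range(n_curves):
        noisy = cb * (1.0 + rng.normal(0.0, noise_sd, cb.shape))
        noisy[cb == 0] = 0.0
        curves.append(ConcentrationCurve(times=times, values=noisy,
                                         compartment="blood"))
    return curves


def _assign_patients(spec: CohortSpec) -> list[tuple[str, str, str, str]]:
    """Deterministic (lesion_id, patient_id, laterality, pathology) tuples.

    Bilateral patients carry two malignant lesions each (mirroring the
    study, where all bilateral cases were in the malignant group); every
    other patient has a single lesion.
    """
    n_bilateral = min(spec.n_bilateral, spec.n_malignant // 2)
    classes = (["malignant"] * spec.n_malignant
               + ["borderline"] * spec.n_borderline
               + ["benign"] * spec.n_benign)
    out = []
    patient = 0
    lesion = 0
    idx = 0
    for _ in range(n_bilateral):
        patient += 1
        for side in ("L", "R"):
            lesion += 1
            out.append((f"LES{lesion:03d}", f"PAT{patient:03d}", side,
                        classes[idx]))
            idx += 1
    while idx < len(classes):
        patient += 1
        lesion += 1
        out.append((f"LES{lesion:03d}", f"PAT{patient:03d}", "L", classes[idx]))
        idx += 1
    return out


def generate_cohort(
    spec: CohortSpec,
    protocol: AcquisitionProtocol = DEFAULT_PROTOCOL,
    aif: AIFModel | None = None,
) -> CohortDataset:
    """Generate the full synthetic cohort for one study run.

    All randomness flows through a single generator seeded with
    ``spec.seed``, so the dataset is bit-reproducible given (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    if aif is None:
        aif = weinmann_aif(dose=protocol.dose_mmol_per_kg,
                           onset_time=protocol.injection_time_s)
    gain = enhancement_gain(aif, protocol, spec.class_params)

    records: list[LesionRecord] = []
    patient_age: dict[str, float] = {}
    for lesion_id, patient_id, side, pathology in _assign_patients(spec):
        truth = sample_lesion_params(pathology, spec, rng, protocol)
        curve = simulate_lesion_curve(truth, aif, protocol, spec.noise_sd,
                                      rng, si0=spec.si0, gain=gain)
        if patient_id not in patient_age:
            mean, sd = spec.class_params[pathology]["age"]
            patient_age[patient_id] = _truncated_draw(mean, sd, 18.0, 90.0, rng)
        records.append(LesionRecord(
            lesion_id=lesion_id, patient_id=patient_id, laterality=side,
            pathology=pathology, age=patient_age[patient_id],
            truth=truth, curve=curve,
        ))

    arterial = simulate_measured_aifs(aif, protocol, spec.n_aif_curves,
                                      spec.aif_noise_sd, rng, gain=gain)
    return CohortDataset(spec=spec, protocol=protocol, aif=aif, gain=gain,
                         records=records, arterial_curves=arterial)


def generate_phantom_volume(
    truth_regions: Sequence[tuple[np.ndarray, PKParams]],
    aif: AIFModel,
    protocol: AcquisitionProtocol,
    noise_sd: float,
    rng: np.random.Generator,
    shape: tuple[int, int, int] = (32, 32, 4),
    si0: float = 100.0,
    gain: float | None = None,
) -> np.ndarray:
    """Build a small 4-D phantom with homogeneous kinetic regions.

    Every voxel of a region follows that region's noiseless curve plus
    independent Gaussian noise; background voxels stay flat at ``si0``.
    Returns an (x, y, z, t) array.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if gain is None:
        gain = enhancement_gain(aif, protocol)
    occupancy = np.zeros(shape, dtype=int)
    for mask, _ in truth_regions:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != shape:
            raise ValueError("region mask shape must match the phantom shape")
        occupancy += mask
    if occupancy.max() > 1:
        raise ValueError("region masks must be disjoint")

    times = protocol.times()
    cp = blood_to_plasma(population_blood_curve(aif, times), aif.hct)
    volume = np.full(shape + (times.size,), si0, dtype=float)
    for mask, truth in truth_regions:
        mask = np.asarray(mask).astype(bool)
        ct = forward_extended_tofts(truth, cp, times)
        volume[mask] = si0 * (1.0 + gain * ct.values)
    if noise_sd > 0:
        peak = volume.max()
        volume = volume + rng.normal(0.0, noise_sd * peak, volume.shape)
    return volume
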