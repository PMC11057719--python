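"""Synthetic-data generators with known ground truth for every stage.

Everything the pipeline consumes can be generated here with full seed
control: reporter constructs, control/sample chromatogram pairs whose true
indel mixture is recorded in a manifest, tissue cohorts whose true outcome
fractions follow preset profiles, and germline progeny tables drawn from
multinomial vial counts.

The chromatogram model is deliberately simple — called-channel peaks are
Gaussian around a common amplitude with optional per-position decay, and
non-called channels carry folded-Gaussian background — because the
decomposition contract only requires the mixture-of-shifts structure.
Raising ``background_sd`` forces quality-control failures on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .germline import OUTCOMES, PHENOTYPE_BY_OUTCOME
from .reference import (
    SACI_MOTIF,
    ReferenceConstruct,
    _count_occurrences,
    build_sce_from_wildtype,
    locate_recognition_site,
)
from .trace import BASES, TraceData

MAX_INDEL_BUDGET = 35  # largest net indel any generator will place


@dataclass(frozen=True)
class TraceSimParams:
    """Chromatogram noise model.

    ``signal_mean``/``signal_sd`` govern the called-channel peak height,
    ``background_sd`` the folded-Gaussian non-called channels, and
    ``decay_rate`` an optional per-position multiplicative amplitude decay
    (0 disables it).
    """

    signal_mean: float = 1.0
    signal_sd: float = 0.05
    background_sd: float = 0.02
    decay_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_sd < 0 or self.background_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 <= self.decay_rate <= 0.01:
            raise ValueError("decay_rate must be in [0, 0.01]")


@dataclass(frozen=True)
class OutcomeProfile:
    """True outcome fractions for one experimental group.

    ``f_noDSB + f_HR + f_NHEJ = 1``.  ``nhej_spectrum`` distributes the
    NHEJ mass over shifts excluding 0 and the HR shift; ``None`` selects
    the default deletion-biased geometric spectrum.
    """

    label: str
    f_noDSB: float
    f_HR: float
    f_NHEJ: float
    nhej_spectrum: dict[int, float] | None = None
    sex: str = ""
    tissue: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        fracs = (self.f_noDSB, self.f_HR, self.f_NHEJ)
        if any(f < 0 or f > 1 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("outcome fractions must be in [0,1] and sum to 1")

    @property
    def rel_hr_truth(self) -> float:
        """True HR percentage of detectable events."""
        det = self.f_HR + self.f_NHEJ
        return float("nan") if det == 0 else 100.0 * self.f_HR / det


@dataclass(frozen=True)
class SimulatedSample:
    """One control/sample trace pair with its recorded truth."""

    sample_id: str
    control: TraceData
    sample: TraceData
    truth: dict[int, float]
    manifest: dict


def default_nhej_spectrum(
    max_indel: int = MAX_INDEL_BUDGET,
    hr_shift: int = -23,
    decay: float = 0.7,
    deletion_bias: float = 2.0,
) -> dict[int, float]:
    """Geometric-decay indel-size distribution, deletion-biased.

    Weight(k) is proportional to ``decay**(|k|-1)``, with deletions
    up-weighted by ``deletion_bias``; zero mass at shift 0 and at the HR
    shift.  Normalized to sum to one.
    """
    raw = {}
    for k in range(-max_indel, max_indel + 1):
        if k == 0 or k == hr_shift:
            continue
        raw[k] = (deletion_bias if k < 0 else 1.0) * decay ** (abs(k) - 1)
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def make_reference(seed: int, amplicon_len: int = 600) -> ReferenceConstruct:
    """Random non-repetitive construct with one SacI site.

    The wild-type amplicon carries GAGCTC exactly once, placed so that the
    default alignment window fits upstream of the break and the
    decomposition window fits downstream for K = 35.
    """
    if amplicon_len < 400:
        raise ValueError("amplicon_len must be >= 400 to accommodate K = 35")
    rng = np.random.default_rng(seed)
    locus = max(110, amplicon_len // 3)  # 0-based index of GAGCTC
    while True:
        seq = "".join(rng.choice(list(BASES), size=amplicon_len))
        wt = seq[:locus] + SACI_MOTIF + seq[locus + len(SACI_MOTIF) :]
        if _count_occurrences(wt, SACI_MOTIF) != 1:
            continue
        sce, recognition_start = build_sce_from_wildtype(wt)
        return ReferenceConstruct(
            wildtype_seq=wt, sce_seq=sce, recognition_start=recognition_start
        )


def _one_hot(seq: str, length: int) -> np.ndarray:
    idx = np.frombuffer(seq[:length].encode("ascii"), dtype=np.uint8)
    lookup = np.zeros(128, dtype=np.int64)
    for i, b in enumerate(BASES):
        lookup[ord(b)] = i
    out = np.zeros((length, 4), dtype=float)
    out[np.arange(length), lookup[idx]] = 1.0
    return out


def _apply_indel(
    sce: str, break_position: int, k: int, rng: np.random.Generator
) -> str:
    """Sequence of a molecule carrying a net indel of k bases at the break."""
    if k == 0:
        return sce
    if k < 0:
        return sce[:break_position] + sce[break_position - k :]
    insert = "".join(rng.choice(list(BASES), size=k))
    return sce[:break_position] + insert + sce[break_position:]


def simulate_trace_pair(
    ref: ReferenceConstruct,
    truth: dict[int, float],
    params: TraceSimParams,
) -> tuple[TraceData, TraceData, dict]:
    """Render a control trace and a truth-weighted mixture sample trace.

    The control is rendered from ``sce_seq``; the sample is the
    truth-weighted sum of indel-shifted renderings with independent noise.
    Both traces span positions 1..len(sce)-35 so every shifted component is
    fully defined.  Returns ``(control, sample, manifest)``.
    """
    weights = {int(k): float(w) for k, w in truth.items() if w > 0}
    if any(w < 0 for w in truth.values()) or abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("truth weights must be >= 0 and sum to 1")
    if any(abs(k) > MAX_INDEL_BUDGET for k in weights):
        raise ValueError(f"truth support must lie within +/-{MAX_INDEL_BUDGET}")
    rng = np.random.default_rng(params.seed)
    sce = ref.sce_seq
    break_position = locate_recognition_site(ref)
    L = len(sce) - MAX_INDEL_BUDGET
    decay = (1.0 - params.decay_rate) ** np.arange(L)[:, None]

    def render(signal: np.ndarray) -> TraceData:
        amp = rng.normal(params.signal_mean, params.signal_sd, size=(L, 4)) * decay
        bg = np.abs(rng.normal(0.0, params.background_sd, size=(L, 4)))
        return TraceData.from_channels(np.clip(signal * amp, 0.0, None) + bg)

    control = render(_one_hot(sce, L))
    mixture = np.zeros((L, 4))
    for k in sorted(weights):
        mixture += weights[k] * _one_hot(_apply_indel(sce, break_position, k, rng), L)
    sample = render(mixture)
    manifest = {
        "truth": weights,
        "seed": params.seed,
        "break_position": break_position,
        "trace_len": L,
        "params": {
            "signal_mean": params.signal_mean,
            "signal_sd": params.signal_sd,
            "background_sd": params.background_sd,
            "decay_rate": params.decay_rate,
        },
    }
    return control, sample, manifest


def profile_truth_spectrum(
    profile: OutcomeProfile, hr_shift: int = -23
) -> dict[int, float]:
    """Expand a profile's outcome fractions into a full shift spectrum."""
    nhej = profile.nhej_spectrum or default_nhej_spectrum(hr_shift=hr_shift)
    if abs(sum(nhej.values()) - 1.0) > 1e-9 or 0 in nhej or hr_shift in nhej:
        raise ValueError("nhej_spectrum must sum to 1 with no mass at 0 or HR")
    truth: dict[int, float] = {}
    if profile.f_noDSB > 0:
        truth[0] = profile.f_noDSB
    if profile.f_HR > 0:
        truth[hr_shift] = profile.f_HR
    for k, w in nhej.items():
        if profile.f_NHEJ * w > 0:
            truth[k] = truth.get(k, 0.0) + profile.f_NHEJ * w
    return truth


def simulate_cohort(
    profile: OutcomeProfile,
    n_samples: int,
    params: TraceSimParams,
    ref: ReferenceConstruct | None = None,
    hr_shift: int = -23,
    jitter_concentration: float | None = 200.0,
) -> list[SimulatedSample]:
    """Simulate a tissue cohort of trace pairs around a profile's truth.

    Per sample the outcome fractions receive a Dirichlet perturbation with
    the given concentration (``None`` disables jitter, making every
    sample's truth equal the profile), then the full spectrum is built and
    a trace pair rendered from a child seed.  Manifests allow exact truth
    recovery.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(params.seed)
    if ref is None:
        ref = make_reference(int(rng.integers(2**31)))
    out = []
    base = np.array([profile.f_noDSB, profile.f_HR, profile.f_NHEJ])
    for i in range(n_samples):
        fracs = base.copy()
        nz = base > 0
        if jitter_concentration and nz.sum() > 1:  # 0/None disable jitter
            fracs[nz] = rng.dirichlet(jitter_concentration * base[nz])
        jittered = replace(
            profile, f_noDSB=fracs[0], f_HR=fracs[1], f_NHEJ=fracs[2]
        )
        truth = profile_truth_spectrum(jittered, hr_shift)
        pair_seed = int(rng.integers(2**31))
        control, sample, manifest = simulate_trace_pair(
            ref, truth, replace(params, seed=pair_seed)
        )
        manifest.update(
            profile=profile.label,
            sex=profile.sex,
            tissue=profile.tissue,
            condition=profile.condition,
            true_fractions={
                "f_noDSB": float(fracs[0]),
                "f_HR": float(fracs[1]),
                "f_NHEJ": float(fracs[2]),
            },
        )
        out.append(
            SimulatedSample(
                sample_id=f"{profile.label}_{i:03d}",
                control=control,
                sample=sample,
                truth=truth,
                manifest=manifest,
            )
        )
    return out


def simulate_germline_counts(
    p: tuple[float, float, float],
    n_vials: int,
    mean_progeny: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vial progeny totals (Poisson, truncated at >= 1) and outcome counts.

    Returns ``(totals, counts)`` with ``counts`` of shape (n_vials, 3) in
    the order HR, NoDSB_NHEJ, SSA.
    """
    p_arr = np.asarray(p, dtype=float)
    if p_arr.shape != (3,) or np.any(p_arr < 0) or abs(p_arr.sum() - 1.0) > 1e-9:
        raise ValueError("p must be three non-negative fractions summing to 1")
    if mean_progeny <= 0 or n_vials < 1:
        raise ValueError("mean_progeny must be > 0 and n_vials >= 1")
    totals = rng.poisson(mean_progeny, size=n_vials)
    while np.any(totals == 0):  # truncate at >= 1 progeny per vial
        zero = totals == 0
        totals[zero] = rng.poisson(mean_progeny, size=int(zero.sum()))
    counts = rng.multinomial(totals, p_arr)
    return totals, counts


def simulate_germline_cohort(
    p: tuple[float, float, float],
    n_vials: int,
    mean_progeny: float,
    seed: int,
    parent_sex: str = "male",
    out_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Render a germline progeny table from multinomial vial counts.

    Phenotypes are the inverse of the scoring map (HR -> red/brown,
    NoDSB_NHEJ -> white/brown, SSA -> white/yellow).  Returns the progeny
    table and a truth manifest; optionally writes the CSV.
    """
    rng = np.random.default_rng(seed)
    totals, counts = simulate_germline_counts(p, n_vials, mean_progeny, rng)
    rows = []
    for i in range(n_vials):
        vial_id = f"{parent_sex[0]}{i + 1:03d}"
        for outcome, c in zip(OUTCOMES, counts[i]):
            eye, body = PHENOTYPE_BY_OUTCOME[outcome]
            rows.extend(
                {
                    "vial_id": vial_id,
                    "parent_sex": parent_sex,
                    "eye_color": eye,
                    "body_color": body,
                }
                for _ in range(int(c))
            )
    progeny = pd.DataFrame(rows)
    manifest = {
        "p": {o: float(x) for o, x in zip(OUTCOMES, p)},
        "n_vials": n_vials,
        "mean_progeny": mean_progeny,
        "seed": seed,
        "parent_sex": parent_sex,
        "total_progeny": int(totals.sum()),
    }
    if out_csv is not None:
        progeny.to_csv(out_csv, index=False)
    return progeny, manifest
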