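"""Synthetic-data generators with known ground truth for every stage.

Every input the pipeline consumes can be generated here with a known plan,
so detection, classification, statistics and power are all testable
without external data:

* :func:`gen_usv_recording` — USV audio as frequency-modulated tones
  (35-125 kHz) synthesized by instantaneous-frequency phase integration,
  with planted syllable boundaries, pitch jumps and additive Gaussian
  noise at a chosen SNR, plus the ground-truth syllable table;
* :func:`gen_sfs` — unfolded site frequency spectra under the neutral
  coalescent, or sweep-distorted spectra where a fraction of mutations is
  reassigned to the extreme classes (excess singletons and high-frequency
  derived alleles), the stylized footprint of a selective sweep;
* :func:`gen_junction_dataset` — binomial junction-read counts at known
  PSI per event and group;
* :func:`gen_cohort` — per-animal syllable feature cohorts drawn from
  genotype-specific mixtures, in the exact table dialect the cohort and
  bimodality modules read.

The default generator parameters are the study conditions of the vocal
phenotype they emulate: an adult "s"-syllable duration mixture of
22.6 +/- 9.1 ms (71%) and 69.0 +/- 40.1 ms (29%), an adult Fq_max mixture
of 80.8 +/- 11.5 kHz (91.5%) and 107.1 +/- 2.1 kHz (8.5%), and pup call
rates of 77.9 (wild-type) vs 62.7 (humanized) calls per minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sfs import FrequencySpectrum, _coalescent_class_lengths

__all__ = [
    "PlannedSegment",
    "PlannedSyllable",
    "SyllablePlan",
    "GenotypeSpec",
    "CohortPlan",
    "random_plan",
    "gen_usv_recording",
    "gen_sfs",
    "gen_junction_dataset",
    "gen_cohort",
    "adult_duration_mixture",
    "adult_fqmax_mixture",
    "pup_call_rates",
    "sample_two_gaussian",
]

USV_BAND = (35_000.0, 125_000.0)

#: junction multiplicities per alternative-splicing type (inclusion, skipping)
AS_JUNCTIONS = {"cass": (2, 1), "alt5": (1, 1), "alt3": (1, 1),
                "taca": (3, 1), "mutx": (2, 2)}


# ---------------------------------------------------------------------------
# USV audio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlannedSegment:
    """One note: linear frequency ramp from f_start to f_end over dur_s."""

    f_start_hz: float
    f_end_hz: float
    dur_s: float


@dataclass(frozen=True)
class PlannedSyllable:
    onset_s: float
    segments: tuple[PlannedSegment, ...]
    amplitude: float = 0.25  # linear, full scale = 1.0

    @property
    def dur_s(self) -> float:
        return sum(seg.dur_s for seg in self.segments)

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.dur_s

    def jumps(self, thresh_hz: float = 10_000.0) -> list[tuple[int, float]]:
        """Planted (direction, magnitude_hz) steps between notes."""
        out = []
        for a, b in zip(self.segments[:-1], self.segments[1:]):
            step = b.f_start_hz - a.f_end_hz
            if abs(step) >= thresh_hz:
                out.append((1 if step > 0 else -1, abs(step)))
        return out

    def label(self, thresh_hz: float = 10_000.0) -> str:
        jumps = self.jumps(thresh_hz)
        if not jumps:
            return "s"
        if len(jumps) == 1:
            return "u" if jumps[0][0] > 0 else "d"
        return "m"


@dataclass
class SyllablePlan:
    """Full description of a synthetic recording."""

    syllables: list[PlannedSyllable]
    rate: int = 250_000
    snr_db: float = 20.0
    seed: int = 0
    tail_s: float = 0.05  # trailing silence after the last syllable

    def __post_init__(self) -> None:
        for syl in self.syllables:
            for seg in syl.segments:
                lo = min(seg.f_start_hz, seg.f_end_hz)
                hi = max(seg.f_start_hz, seg.f_end_hz)
                if lo < USV_BAND[0] or hi > USV_BAND[1]:
                    raise ValueError(
                        f"segment {seg} outside the USV band {USV_BAND}")

    @property
    def duration_s(self) -> float:
        last = max((s.offset_s for s in self.syllables), default=0.0)
        return last + self.tail_s

    def truth_table(self, jump_thresh_hz: float = 10_000.0) -> pd.DataFrame:
        rows = []
        for syl in self.syllables:
            freqs = [f for seg in syl.segments
                     for f in (seg.f_start_hz, seg.f_end_hz)]
            rows.append({
                "onset_s": syl.onset_s,
                "offset_s": syl.offset_s,
                "class": syl.label(jump_thresh_hz),
                "n_jumps": len(syl.jumps(jump_thresh_hz)),
                "fq_min_khz": min(freqs) / 1000.0,
                "fq_max_khz": max(freqs) / 1000.0,
                "amplitude": syl.amplitude,
            })
        return pd.DataFrame(rows)


def random_plan(n_syllables: int, seed: int = 0, rate: int = 250_000,
                snr_db: float = 20.0,
                classes: tuple[str, ...] = ("s", "u", "d", "m"),
                dur_range_ms: tuple[float, float] = (25.0, 70.0),
                gap_range_ms: tuple[float, float] = (30.0, 90.0),
                jump_range_khz: tuple[float, float] = (15.0, 25.0),
                chirp_slope_khz_ms: float = 0.3) -> SyllablePlan:
    """Random syllable plan with balanced classes and in-band pitch tracks.

    Jump magnitudes stay well above the 10 kHz detection threshold and all
    notes remain inside 40-120 kHz so band edges never clip a track.
    """
    rng = np.random.default_rng(seed)
    t = 0.05
    syllables = []
    for k in range(n_syllables):
        cls = classes[k % len(classes)]
        n_jumps = {"s": 0, "u": 1, "d": 1, "m": int(rng.integers(2, 4))}[cls]
        n_segs = n_jumps + 1
        total_ms = float(rng.uniform(*dur_range_ms))
        seg_ms = np.full(n_segs, total_ms / n_segs)
        f = float(rng.uniform(55_000, 90_000))
        if cls == "d":
            directions = [-1]
        elif cls == "u":
            directions = [1]
        else:
            directions = [1 if i % 2 == 0 else -1 for i in range(n_jumps)]
            rng.shuffle(directions)
        segments = []
        for i in range(n_segs):
            slope = float(rng.uniform(-chirp_slope_khz_ms,
                                      chirp_slope_khz_ms)) * 1000.0
            f_end = np.clip(f + slope * seg_ms[i], 42_000, 118_000)
            segments.append(PlannedSegment(f, float(f_end), seg_ms[i] / 1000))
            if i < n_jumps:
                mag = float(rng.uniform(*jump_range_khz)) * 1000.0
                step = directions[i] * mag
                nxt = float(np.clip(f_end + step, 42_000, 118_000))
                if abs(nxt - f_end) < jump_range_khz[0] * 1000.0:
                    nxt = float(f_end - directions[i] * mag)  # bounce inward
                    directions[i] = 1 if nxt > f_end else -1
                f = nxt
        syllables.append(PlannedSyllable(onset_s=t, segments=tuple(segments)))
        t += total_ms / 1000.0 + float(rng.uniform(*gap_range_ms)) / 1000.0
    return SyllablePlan(syllables=syllables, rate=rate, snr_db=snr_db,
                        seed=seed)


def gen_usv_recording(plan: SyllablePlan
                      ) -> tuple[np.ndarray, int, pd.DataFrame]:
    """Synthesize the planned recording.

    Each note's instantaneous frequency is integrated into a continuous
    phase, so pitch is smooth within notes and steps exactly at planted
    jumps; white Gaussian noise is added at the planned SNR (measured
    against the tone RMS).  Returns (samples, rate, truth table).
    """
    rate = plan.rate
    n = int(np.ceil(plan.duration_s * rate)) + 1
    rng = np.random.default_rng(plan.seed)
    amp_ref = max((s.amplitude for s in plan.syllables), default=0.25)
    sigma = (amp_ref / np.sqrt(2.0)) * 10.0 ** (-plan.snr_db / 20.0)
    samples = rng.normal(0.0, sigma, size=n)
    for syl in plan.syllables:
        start = int(round(syl.onset_s * rate))
        freq_parts = []
        for seg in syl.segments:
            m = max(int(round(seg.dur_s * rate)), 1)
            freq_parts.append(np.linspace(seg.f_start_hz, seg.f_end_hz, m,
                                          endpoint=False))
        freq = np.concatenate(freq_parts)
        stop = min(start + freq.size, n)
        freq = freq[:stop - start]
        phase = 2.0 * np.pi * np.cumsum(freq) / rate
        samples[start:stop] += syl.amplitude * np.sin(phase)
    return samples, rate, plan.truth_table()


# ---------------------------------------------------------------------------
# Site frequency spectra
# ---------------------------------------------------------------------------


def gen_sfs(n: int, S: int, regime: str = "neutral", lam: float = 0.0,
            seed: int = 0) -> FrequencySpectrum:
    """One synthetic unfolded SFS.

    ``regime="neutral"`` draws a Kingman genealogy and places ``S``
    mutations multinomially along it.  ``regime="sweep"`` additionally
    reassigns each mutation with probability ``lam`` to class 1 or
    ``n - 1`` (equal odds) — the stylized post-sweep excess of singletons
    and high-frequency derived variants.
    """
    if regime not in ("neutral", "sweep"):
        raise ValueError(f"unknown regime {regime!r}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must be in [0, 1]")
    if regime == "neutral" and lam != 0.0:
        raise ValueError("neutral regime requires lam = 0")
    rng = np.random.default_rng(seed)
    lengths = _coalescent_class_lengths(n, rng)
    xi = rng.multinomial(S, lengths / lengths.sum()).astype(float)
    if regime == "sweep" and lam > 0:
        moved_total = 0
        for i in range(n - 1):
            stay = rng.binomial(int(xi[i]), 1.0 - lam)
            moved_total += int(xi[i]) - stay
            xi[i] = stay
        to_singleton = rng.binomial(moved_total, 0.5)
        xi[0] += to_singleton
        xi[n - 2] += moved_total - to_singleton
    return FrequencySpectrum(n=n, xi=xi)


# ---------------------------------------------------------------------------
# Junction counts
# ---------------------------------------------------------------------------


def gen_junction_dataset(true_psi, depth: int = 100, delta=0.0,
                         seed: int = 0, as_types=None,
                         genes=None) -> pd.DataFrame:
    """Binomial junction-read table for two groups at known PSI.

    Per event and group, the number of inclusion isoform molecules is
    Binomial(depth, psi); raw junction reads are molecules times the
    junction multiplicity of the event's splicing type, so the
    multiplicity-normalized PSI estimator is exactly invertible.
    Group B's true PSI is ``true_psi + delta`` (scalar or per-event).
    """
    psi_a = np.atleast_1d(np.asarray(true_psi, dtype=float))
    psi_b = psi_a + np.broadcast_to(np.asarray(delta, dtype=float),
                                    psi_a.shape)
    if np.any((psi_a < 0) | (psi_a > 1) | (psi_b < 0) | (psi_b > 1)):
        raise ValueError("PSI and PSI + delta must lie in [0, 1]")
    n_events = psi_a.size
    if as_types is None:
        as_types = ["cass"] * n_events
    if genes is None:
        genes = [f"gene{i:05d}" for i in range(n_events)]
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_events):
        n_inc, n_skip = AS_JUNCTIONS[as_types[i]]
        for group, psi in (("A", psi_a[i]), ("B", psi_b[i])):
            k = rng.binomial(depth, psi)
            rows.append({
                "event_id": f"ev{i:05d}", "gene": genes[i],
                "as_type": as_types[i], "group": group,
                "inc_reads": int(k * n_inc),
                "skip_reads": int((depth - k) * n_skip),
                "n_inc_junctions": n_inc, "n_skip_junctions": n_skip,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Syllable cohorts
# ---------------------------------------------------------------------------


def adult_duration_mixture() -> dict:
    """Adult "s"-syllable duration mixture (ms).

    Component parameters are chosen so the observable split statistics of
    the mixture match the adult courtship phenotype: weighted-density
    intersection (the short/long cutoff) at 44 ms, 29% of syllables long,
    and split-group means of 22.6 ms (short) and 69.0 ms (long).
    """
    return {"w": (0.702, 0.298), "mu": (22.53, 67.92),
            "sigma": (9.37, 14.76)}


def adult_fqmax_mixture() -> dict:
    """Adult Fq_max mixture (kHz): main 80.8 +/- 11.5 (91.5%), high
    107.1 +/- 2.1 (8.5%); the main component is truncated below 100 kHz
    because the high-Fq_max calls form a distinct population."""
    return {"w": (0.915, 0.085), "mu": (80.8, 107.1), "sigma": (11.5, 2.1),
            "trunc_low_below": 100.0}


def pup_u_fqmax_mixture() -> dict:
    """Pup "u"-syllable Fq_max mixture (kHz) at weak separation.

    The pup "u" syllables are the one class whose two Fq_max peaks are not
    well separated (Ashman's D = 1.603, below the D > 2 bimodality
    criterion).  Component spread and weights are representative choices;
    the center gap is set so the mixture's separation score is exactly
    1.603: dmu = D / sqrt(2) * sqrt(s1^2 + s2^2).
    """
    s1, s2 = 6.0, 7.0
    dmu = 1.603 / np.sqrt(2.0) * np.sqrt(s1**2 + s2**2)
    return {"w": (0.5, 0.5), "mu": (70.0, 70.0 + dmu), "sigma": (s1, s2)}


def pup_call_rates() -> dict[str, float]:
    """Pup isolation-call rates (calls/min) by genotype."""
    return {"wt/wt": 77.9, "hu/wt": 70.3, "hu/hu": 62.7}


def sample_two_gaussian(n: int, w, mu, sigma, rng: np.random.Generator,
                        trunc_low_below: float | None = None,
                        floor: float | None = None) -> np.ndarray:
    """Draw from a two-component Gaussian mixture.

    ``trunc_low_below`` truncates the *low* component above that value
    (rejection sampling), keeping the two populations distinct;
    ``floor`` truncates both components below a physical minimum.
    """
    comp = rng.random(n) < w[1]
    out = np.where(comp,
                   rng.normal(mu[1], sigma[1], n),
                   rng.normal(mu[0], sigma[0], n))
    for _ in range(100):
        bad = np.zeros(n, dtype=bool)
        if trunc_low_below is not None:
            bad |= (~comp) & (out >= trunc_low_below)
        if floor is not None:
            bad |= out < floor
        if not bad.any():
            break
        lo = bad & ~comp
        hi = bad & comp
        out[lo] = rng.normal(mu[0], sigma[0], int(lo.sum()))
        out[hi] = rng.normal(mu[1], sigma[1], int(hi.sum()))
    return out


@dataclass
class GenotypeSpec:
    """Generative settings for one genotype."""

    n_animals: int
    sessions: int = 1
    call_rate_per_min: float = 77.9
    session_min: float = 5.0
    class_probs: dict = field(default_factory=lambda: {
        "s": 0.6, "u": 0.15, "d": 0.15, "m": 0.1})
    fqmax_mixture: dict = field(default_factory=adult_fqmax_mixture)
    duration_mixture: dict = field(default_factory=adult_duration_mixture)
    amplitude_db: tuple[float, float] = (-40.0, 5.0)  # mean, sd


@dataclass
class CohortPlan:
    genotypes: dict[str, GenotypeSpec]
    seed: int = 0


def gen_cohort(plan: CohortPlan) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize a cohort syllable table and its animal metadata.

    Per animal and session the number of syllables is Poisson with mean
    ``call_rate_per_min * session_min``; classes are multinomial and the
    feature values are mixture draws.  Output tables use the exact dialect
    the cohort-statistics and bimodality modules read.
    """
    rng = np.random.default_rng(plan.seed)
    syl_rows = []
    meta_rows = []
    animal_no = 0
    for genotype, spec in plan.genotypes.items():
        classes = list(spec.class_probs)
        probs = np.array([spec.class_probs[c] for c in classes], dtype=float)
        probs = probs / probs.sum()
        for _ in range(spec.n_animals):
            animal_no += 1
            animal_id = f"an{animal_no:03d}"
            meta_rows.append({"animal_id": animal_id, "genotype": genotype,
                              "sessions": spec.sessions})
            for session in range(1, spec.sessions + 1):
                n_syl = rng.poisson(spec.call_rate_per_min * spec.session_min)
                if n_syl == 0:
                    continue
                cls = rng.choice(classes, size=n_syl, p=probs)
                fm = spec.fqmax_mixture
                fqmax = sample_two_gaussian(
                    n_syl, fm["w"], fm["mu"], fm["sigma"], rng,
                    trunc_low_below=fm.get("trunc_low_below"),
                    floor=USV_BAND[0] / 1000.0)
                dm = spec.duration_mixture
                dur = sample_two_gaussian(
                    n_syl, dm["w"], dm["mu"], dm["sigma"], rng,
                    trunc_low_below=dm.get("trunc_low_below"), floor=3.0)
                amp = rng.normal(*spec.amplitude_db, size=n_syl)
                for j in range(n_syl):
                    syl_rows.append({
                        "animal_id": animal_id, "genotype": genotype,
                        "session": session, "class": cls[j],
                        "duration_ms": float(dur[j]),
                        "fq_max_khz": float(fqmax[j]),
                        "amplitude_db": float(amp[j]),
                    })
    return pd.DataFrame(syl_rows), pd.DataFrame(meta_rows)
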