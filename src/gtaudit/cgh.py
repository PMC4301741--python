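"""Tiling-array CGH: probe design, normalization, smoothing, aberration calls.

Two-channel (test Cy5 / reference Cy3) intensities over 60-mer probes tiled
across a host region (one strand, 60 bp step) and a vector (both strands,
5 bp step) are normalized per channel by the median of 13 control probes,
converted to log2 ratios, smoothed with centered moving averages, and
segmented into aberrant intervals with a z-like interval score.  A vector
insertion shows as a uniformly elevated vector-probe track, and a
homozygous insertion doubles the ratio of a heterozygous one (log2
difference of 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dnautil import revcomp

PROBE_LENGTH = 60
N_CONTROL_PROBES = 13


@dataclass(frozen=True)
class Probe:
    probe_id: str
    source: str          # host_region | vector_forward | vector_reverse | control
    start: int | None    # 0-based on source; None for controls
    sequence: str

    def __post_init__(self) -> None:
        if self.source != "control" and len(self.sequence) != PROBE_LENGTH:
            raise ValueError("probes must be 60-mers")
        if (self.start is None) != (self.source == "control"):
            raise ValueError("controls (and only controls) have no coordinate")


@dataclass
class ProbeSet:
    probes: list[Probe]

    def by_source(self, source: str) -> list[Probe]:
        return [p for p in self.probes if p.source == source]

    @property
    def control_ids(self) -> list[str]:
        return [p.probe_id for p in self.by_source("control")]


def design_probes(
    host_region: str,
    vector: str,
    probe_length: int = PROBE_LENGTH,
    host_step: int = 60,
    vector_step: int = 5,
) -> ProbeSet:
    """Tile the host region (forward strand) and vector (both strands).

    Host probes start every ``host_step`` bp; vector probes every
    ``vector_step`` bp on each strand (the dense overlapping tiling that
    makes small insertions visible).  13 control probes are appended.
    """
    if host_step <= 0 or vector_step <= 0:
        raise ValueError("steps must be positive")
    if len(host_region) < probe_length or len(vector) < probe_length:
        raise ValueError("sources must be longer than the probe length")
    probes: list[Probe] = []
    for i, s in enumerate(range(0, len(host_region) - probe_length + 1, host_step)):
        probes.append(Probe(f"host_{i:05d}", "host_region", s,
                            host_region[s:s + probe_length]))
    vec_rc = revcomp(vector)
    for strand, seq, tag in (("+", vector, "vfwd"), ("-", vec_rc, "vrev")):
        source = "vector_forward" if strand == "+" else "vector_reverse"
        for i, s in enumerate(range(0, len(seq) - probe_length + 1, vector_step)):
            probes.append(Probe(f"{tag}_{i:05d}", source, s, seq[s:s + probe_length]))
    rng = np.random.default_rng(13)  # fixed control sequences, design-time only
    for i in range(N_CONTROL_PROBES):
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, probe_length))
        probes.append(Probe(f"control_{i:02d}", "control", None, seq))
    return ProbeSet(probes)


@dataclass
class ArrayResult:
    """Normalized two-channel signals and log2 ratios, ordered as the probe set."""

    probes: ProbeSet
    test_norm: np.ndarray
    ref_norm: np.ndarray
    log2_ratio: np.ndarray

    def track(self, source: str) -> tuple[list[Probe], np.ndarray]:
        idx = [i for i, p in enumerate(self.probes.probes) if p.source == source]
        return [self.probes.probes[i] for i in idx], self.log2_ratio[idx]


def normalize_and_ratio(
    probes: ProbeSet,
    test_raw: np.ndarray,
    ref_raw: np.ndarray,
    ref_floor_fraction: float = 1e-6,
) -> ArrayResult:
    """Per-channel control-median normalization and log2 ratio.

    Each channel is divided by the median intensity of its control probes
    (removing global dye/scanner scale); the reference channel is floored
    at ``ref_floor_fraction`` of its control median so ratios stay finite.
    """
    test_raw = np.asarray(test_raw, dtype=float)
    ref_raw = np.asarray(ref_raw, dtype=float)
    ctrl = [i for i, p in enumerate(probes.probes) if p.source == "control"]
    if not ctrl:
        raise ValueError("probe set has no control probes")
    t_med = float(np.median(test_raw[ctrl]))
    r_med = float(np.median(ref_raw[ctrl]))
    if t_med <= 0 or r_med <= 0:
        raise ValueError("control median is zero; cannot normalize")
    test_norm = test_raw / t_med
    ref_norm = ref_raw / r_med
    ratio = test_norm / np.maximum(ref_norm, ref_floor_fraction)
    return ArrayResult(probes, test_norm, ref_norm, np.log2(ratio))


def moving_average(values: np.ndarray, window_probes: int) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at ends.

    At position i the mean is taken over i +/- h where
    h = min((window-1)//2, i, n-1-i), so a window of 1 is the identity and
    interior points see the full window.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if window_probes < 1:
        raise ValueError("window must be >= 1")
    h_max = (window_probes - 1) // 2
    out = np.empty(n)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    for i in range(n):
        h = min(h_max, i, n - 1 - i)
        out[i] = (cs[i + h + 1] - cs[i - h]) / (2 * h + 1)
    return out


@dataclass(frozen=True)
class AberrationCall:
    start_index: int          # probe index within the track, inclusive
    end_index: int            # exclusive
    n_probes: int
    mean_log2: float
    score: float


def robust_sd(values: np.ndarray) -> float:
    """MAD-based spread estimate (consistent for a normal distribution)."""
    x = np.asarray(values, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def call_aberrations(
    track: np.ndarray,
    min_probes: int = 5,
    score_threshold: float = 4.0,
    fuzzy_zero_floor: float = 0.3,
) -> list[AberrationCall]:
    """Segment a smoothed log2 track into aberrant intervals.

    Maximal runs of same-sign deviation are scored |mean| * sqrt(n) /
    robust-SD(track); runs below ``score_threshold``, shorter than
    ``min_probes``, or with |mean| under the fuzzy-zero floor are dropped.
    A zero-variance track falls back to the |mean| >= floor test alone.
    """
    x = np.asarray(track, dtype=float)
    if len(x) < min_probes:
        raise ValueError(f"track has fewer than {min_probes} probes")
    sd = robust_sd(x)
    signs = np.sign(x)
    calls: list[AberrationCall] = []
    i = 0
    while i < len(x):
        if signs[i] == 0:
            i += 1
            continue
        j = i
        while j < len(x) and signs[j] == signs[i]:
            j += 1
        n = j - i
        mean = float(x[i:j].mean())
        if n >= min_probes and abs(mean) >= fuzzy_zero_floor:
            score = abs(mean) * np.sqrt(n) / sd if sd > 0 else np.inf
            if score >= score_threshold:
                calls.append(AberrationCall(i, j, n, mean, float(score)))
        i = j
    return calls


def copy_state(
    mean_log2: float,
    context: str = "host",
    companion_mean: float | None = None,
    tolerance: float = 0.2,
    doubling_tolerance: float = 0.3,
) -> str:
    """Copy-state label from a mean log2 ratio.

    Host context: conventional CGH bands (one-copy gain +0.6, two-copy
    gain >= +1, one-copy loss -1, two-copy loss <= -2), each with a
    +/- ``tolerance`` band.  Vector context: a detected insertion is
    called homozygous when its mean exceeds a heterozygous companion
    line's by a log2 difference of 1 (ratio doubled), heterozygous when it
    matches the companion; otherwise present_unresolved.
    """
    if not np.isfinite(mean_log2):
        raise ValueError("mean_log2 must be finite")
    if context == "host":
        if mean_log2 >= 1.0 - tolerance:
            return "two_copy_gain"
        if abs(mean_log2 - 0.6) <= tolerance:
            return "one_copy_gain"
        if mean_log2 <= -2.0 + tolerance:
            return "two_copy_loss"
        if abs(mean_log2 + 1.0) <= tolerance:
            return "one_copy_loss"
        if abs(mean_log2) <= tolerance:
            return "neutral"
        return "indeterminate"
    if context == "vector":
        if companion_mean is None:
            return "present"
        diff = mean_log2 - companion_mean
        if abs(diff - 1.0) <= doubling_tolerance:
            return "hom"
        if abs(diff) <= doubling_tolerance:
            return "het"
        if abs(diff + 1.0) <= doubling_tolerance:
            return "het_of_hom_companion"
        return "present_unresolved"
    raise ValueError(f"unknown context {context!r}")
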