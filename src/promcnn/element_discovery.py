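"""Random-substitution profiling and sequence-logo information content.

The random-substitution procedure locates positionally conserved
functional elements (TATA-box, bacterial -10/-35 boxes, ...) learned by a
trained classifier: slide a window of length L (default 6 nt, stride 1)
across the promoter windows, replace the window content of every promoter
with freshly drawn random bases, re-classify, and record the resulting
sensitivity.  Positions whose substitution drastically lowers sensitivity
mark sequence the model depends on; the profile's dips therefore localize
conserved elements without any prior knowledge of promoter features.

Profiles index windows by their start position (1-based, with the
TSS-relative equivalent alongside); each profile point averages
``replicates`` independent substitutions, drawn independently per record.

The companion information-content profile is the sequence-logo statistic:
per alignment column, IC = 2 + sum_b p_b log2 p_b bits, between 0
(uniform column) and 2 (invariant column).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .cnn_model import ModelParameters, predict_classes
from .errors import ConfigurationError, DataError
from .sequence_io import ALPHABET, SequenceRecord, encode_batch

Classifier = Callable[[np.ndarray], np.ndarray]
"""Anything mapping a (batch, length, 4) one-hot array to a binary class
vector (1 = promoter).  A :class:`ModelParameters` is accepted wherever a
Classifier is."""


@dataclass
class SubstitutionProfile:
    window_length: int
    window_starts: np.ndarray  # 1-based start positions x1 (x2 = x1 + L - 1)
    tss_relative_starts: np.ndarray
    sensitivities: np.ndarray  # mean Sn per window start, in [0, 1]
    standard_errors: np.ndarray  # SE of the replicate mean
    baseline_sensitivity: float  # Sn with no substitution
    replicates: int
    seed: int
    n_promoters: int

    def argmin_window(self) -> tuple[int, int]:
        """1-based (start, end) of the window with the lowest sensitivity."""
        i = int(np.argmin(self.sensitivities))
        start = int(self.window_starts[i])
        return start, start + self.window_length - 1


@dataclass
class InformationProfile:
    information_bits: np.ndarray  # per position, in [0, 2]
    base_frequencies: np.ndarray  # positions x 4, columns A, T, G, C
    n_sequences: int
    tss_index: int | None = None


def _as_classifier(model: ModelParameters | Classifier) -> Classifier:
    if isinstance(model, ModelParameters):
        return lambda batch: predict_classes(model, batch)
    if callable(model):
        return model
    raise ConfigurationError(f"expected ModelParameters or a callable, got {type(model)!r}")


def substitution_profile(
    model: ModelParameters | Classifier,
    promoters: Sequence[SequenceRecord],
    window_length: int = 6,
    replicates: int = 10,
    seed: int = 0,
    background: Sequence[float] | None = None,
) -> SubstitutionProfile:
    """Sensitivity profile under sliding-window random substitution.

    For each window start (stride 1), every promoter's window is replaced
    by a random sequence — uniform over A/T/G/C by default, or drawn from
    ``background`` (A, T, G, C probabilities) — independently per record
    and per replicate; the set is re-classified and sensitivity averaged
    over ``replicates``.  Deterministic given ``seed``.
    """
    if not promoters:
        raise DataError("substitution profile needs at least one promoter sequence")
    classify_fn = _as_classifier(model)
    batch = encode_batch(promoters)
    n_rec, seq_len, _ = batch.shape
    if not 1 <= window_length <= seq_len:
        raise DataError(
            f"window_length {window_length} outside 1..{seq_len} (sequence length)"
        )
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=np.float64)
    if bg.shape != (4,) or (bg < 0).any() or abs(bg.sum() - 1.0) > 1e-9:
        raise ConfigurationError("background must be 4 probabilities summing to 1")

    baseline = float(np.mean(classify_fn(batch) == 1))
    rng = np.random.default_rng(seed)
    n_windows = seq_len - window_length + 1
    eye = np.eye(4)
    means = np.empty(n_windows)
    ses = np.empty(n_windows)
    for w in range(n_windows):
        sn = np.empty(replicates)
        for rep in range(replicates):
            codes = rng.choice(4, size=(n_rec, window_length), p=bg)
            modified = batch.copy()
            modified[:, w : w + window_length, :] = eye[codes]
            sn[rep] = np.mean(classify_fn(modified) == 1)
        means[w] = sn.mean()
        ses[w] = sn.std(ddof=1) / np.sqrt(replicates) if replicates > 1 else 0.0

    starts = np.arange(1, n_windows + 1)
    tss = promoters[0].tss_index
    tss_starts = starts - tss if tss is not None else starts.copy()
    return SubstitutionProfile(
        window_length=window_length,
        window_starts=starts,
        tss_relative_starts=tss_starts,
        sensitivities=means,
        standard_errors=ses,
        baseline_sensitivity=baseline,
        replicates=replicates,
        seed=seed,
        n_promoters=n_rec,
    )


def profile_minima(
    profile: SubstitutionProfile, drop_fraction: float = 0.5
) -> list[tuple[int, int]]:
    """TSS-relative intervals where substitution costs at least
    ``drop_fraction`` of the baseline sensitivity.

    Window starts with sensitivity <= (1 - drop_fraction) * baseline are
    grouped into maximal runs; each run is reported as the union of the
    sequence positions its windows cover, converted to TSS-relative
    coordinates; overlapping covers are merged, so returned intervals are
    disjoint.
    """
    if profile.baseline_sensitivity <= 0:
        raise DataError("baseline sensitivity is 0; profile is uninformative")
    if not 0 < drop_fraction <= 1:
        raise ConfigurationError("drop_fraction must be in (0, 1]")
    threshold = (1.0 - drop_fraction) * profile.baseline_sensitivity
    hit = profile.sensitivities <= threshold
    L = profile.window_length
    offset = profile.tss_relative_starts[0] - profile.window_starts[0]
    intervals: list[tuple[int, int]] = []
    i = 0
    n = len(hit)
    while i < n:
        if hit[i]:
            j = i
            while j + 1 < n and hit[j + 1]:
                j += 1
            lo = int(profile.window_starts[i] + offset)
            hi = int(profile.window_starts[j] + offset) + L - 1
            if intervals and lo <= intervals[-1][1] + 1:
                intervals[-1] = (intervals[-1][0], max(intervals[-1][1], hi))
            else:
                intervals.append((lo, hi))
            i = j + 1
        else:
            i += 1
    return intervals


def information_profile(
    sequences: Sequence[SequenceRecord],
    small_sample_correction: bool = False,
) -> InformationProfile:
    """Per-position information content of an aligned sequence set.

    IC = 2 + sum_b p_b log2 p_b over observed base frequencies; N bases
    are excluded from column counts.  The optional Schneider-style
    small-sample correction subtracts e(n) = 3 / (2 n ln 2) per column
    (clipped at 0); it is off by default, being negligible at the corpus
    sizes this package targets.
    """
    if not sequences:
        raise DataError("information profile needs at least one sequence")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise DataError(f"sequences have mixed lengths {sorted(lengths)}")
    (seq_len,) = lengths
    counts = np.zeros((seq_len, 4))
    base_col = {b: i for i, b in enumerate(ALPHABET)}
    for rec in sequences:
        for pos, base in enumerate(rec.sequence):
            if base != "N":
                counts[pos, base_col[base]] += 1
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise DataError("a column contains only N bases; information content undefined")
    freqs = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    if small_sample_correction:
        ic = np.maximum(ic - 3.0 / (2.0 * np.log(2.0) * totals), 0.0)
    return InformationProfile(
        information_bits=ic,
        base_frequencies=freqs,
        n_sequences=len(sequences),
        tss_index=sequences[0].tss_index,
    )


def write_profile(profile: SubstitutionProfile, path) -> None:
    """Delimited profile table; windows indexed by 1-based start position."""
    with open(path, "w") as handle:
        handle.write(
            "# random-substitution sensitivity profile; windows indexed by start "
            f"(1-based), window_length={profile.window_length}, stride=1, "
            f"replicates={profile.replicates}, seed={profile.seed}, "
            f"baseline_Sn={profile.baseline_sensitivity:.4f}, "
            f"n_promoters={profile.n_promoters}\n"
        )
        handle.write("# window_start\ttss_relative_start\tmean_Sn\tSE\treplicates\n")
        for i in range(len(profile.window_starts)):
            handle.write(
                f"{profile.window_starts[i]}\t{profile.tss_relative_starts[i]}\t"
                f"{profile.sensitivities[i]:.4f}\t{profile.standard_errors[i]:.4f}\t"
                f"{profile.replicates}\n"
            )


def write_information_profile(profile: InformationProfile, path) -> None:
    """Delimited logo table: per-position base frequencies and IC in bits."""
    with open(path, "w") as handle:
        handle.write(
            f"# per-position base frequencies and information content (bits); "
            f"n_sequences={profile.n_sequences}\n"
        )
        handle.write("# position\ttss_relative\tfreq_A\tfreq_T\tfreq_G\tfreq_C\tIC_bits\n")
        for i, (row, ic) in enumerate(zip(profile.base_frequencies, profile.information_bits)):
            pos = i + 1
            rel = pos - profile.tss_index if profile.tss_index is not None else pos
            handle.write(
                f"{pos}\t{rel}\t" + "\t".join(f"{v:.4f}" for v in row) + f"\t{ic:.4f}\n"
            )
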