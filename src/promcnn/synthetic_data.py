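"""Synthetic promoter / non-promoter corpora with PWM motifs planted at
TSS-relative offsets.

Promoter windows are background draws with one or more motif instances —
sampled from position weight matrices (PWMs) — overwritten at fixed
TSS-relative offsets (optionally jittered uniformly by a few positions).
Non-promoter windows are background only, or optionally "coding-like"
(3-periodic base composition) for a compositionally structured negative
class.  This emulates the statistical skeleton of curated promoter
corpora: positionally conserved elements such as a TATA-box ~30 bp
upstream of the TSS, or bacterial -10/-35 boxes, against an uninformative
flank — so the whole train/evaluate/profile pipeline is testable without
any external download.

All PWMs use column order A, T, G, C.  TSS-relative coordinate r maps to
1-based window position p = r + tss_index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DataError
from .sequence_io import (
    ALPHABET,
    NONPROMOTER,
    PROMOTER,
    SequenceRecord,
)

_BASES = np.array(list(ALPHABET))


def consensus_pwm(consensus: str, weight: float = 0.9) -> np.ndarray:
    """PWM giving probability `weight` to each consensus base, the rest uniform."""
    if not 0.25 <= weight <= 1.0:
        raise ConfigurationError(f"consensus weight must be in [0.25, 1], got {weight}")
    consensus = consensus.upper()
    off = (1.0 - weight) / 3.0
    pwm = np.full((len(consensus), 4), off)
    for i, base in enumerate(consensus):
        if base not in ALPHABET:
            raise ConfigurationError(f"consensus base {base!r} not in {ALPHABET}")
        pwm[i, ALPHABET.index(base)] = weight
    return pwm


@dataclass(frozen=True)
class MotifModel:
    """A PWM planted at a fixed TSS-relative offset.

    ``offset`` is the TSS-relative coordinate of the motif's first
    position (e.g. -30 for a TATA-box).  ``offset_jitter`` is the maximum
    uniform integer shift in either direction.
    """

    name: str
    pwm: np.ndarray
    offset: int
    offset_jitter: int = 0

    def __post_init__(self) -> None:
        pwm = np.asarray(self.pwm, dtype=np.float64)
        if pwm.ndim != 2 or pwm.shape[1] != 4:
            raise ConfigurationError(f"motif {self.name!r}: pwm must be w x 4, got {pwm.shape}")
        if (pwm < 0).any():
            raise ConfigurationError(f"motif {self.name!r}: pwm entries must be >= 0")
        if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError(f"motif {self.name!r}: pwm rows must sum to 1")
        if self.offset_jitter < 0:
            raise ConfigurationError(f"motif {self.name!r}: jitter must be >= 0")
        object.__setattr__(self, "pwm", pwm)

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.pwm.argmax(axis=1))


# Shipped test fixtures — consensus-weighted toy motifs, not claims about biology.
def tata_box(weight: float = 0.9, offset: int = -30, jitter: int = 0) -> MotifModel:
    return MotifModel("TATA-box", consensus_pwm("TATAAAAG", weight), offset, jitter)


def initiator(weight: float = 0.9, offset: int = -1, jitter: int = 0) -> MotifModel:
    return MotifModel("Inr-like", consensus_pwm("TCAG", weight), offset, jitter)


def minus10_box(weight: float = 0.9, offset: int = -10, jitter: int = 0) -> MotifModel:
    return MotifModel("-10 box", consensus_pwm("TATAAT", weight), offset, jitter)


def minus35_box(weight: float = 0.9, offset: int = -35, jitter: int = 0) -> MotifModel:
    return MotifModel("-35 box", consensus_pwm("TTGACA", weight), offset, jitter)


BUILTIN_MOTIFS = {
    "tata": tata_box,
    "inr": initiator,
    "minus10": minus10_box,
    "minus35": minus35_box,
}


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic labeled corpus."""

    n_promoters: int
    n_nonpromoters: int
    window_length: int = 251
    tss_index: int = 201
    motifs: tuple[MotifModel, ...] = ()
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    negative_mode: str = "background"  # or "coding_like"

    def __post_init__(self) -> None:
        if self.n_promoters < 0 or self.n_nonpromoters < 0:
            raise ConfigurationError("record counts must be >= 0")
        if self.window_length < 1:
            raise ConfigurationError("window_length must be >= 1")
        if not 1 <= self.tss_index <= self.window_length:
            raise ConfigurationError(
                f"tss_index {self.tss_index} outside 1..{self.window_length}"
            )
        bg = np.asarray(self.background, dtype=np.float64)
        if bg.shape != (4,) or (bg < 0).any() or abs(bg.sum() - 1.0) > 1e-9:
            raise ConfigurationError("background must be 4 probabilities summing to 1")
        if self.negative_mode not in ("background", "coding_like"):
            raise ConfigurationError(f"unknown negative_mode {self.negative_mode!r}")
        object.__setattr__(self, "motifs", tuple(self.motifs))
        for motif in self.motifs:
            lo, hi = self.tss_relative_range()
            span_lo = motif.offset - motif.offset_jitter
            span_hi = motif.offset + motif.offset_jitter + motif.width - 1
            if span_lo < lo or span_hi > hi:
                raise ConfigurationError(
                    f"motif {motif.name!r} span [{span_lo}, {span_hi}] (TSS-relative, "
                    f"jitter included) outside window range [{lo}, {hi}]"
                )

    def tss_relative_range(self) -> tuple[int, int]:
        """TSS-relative coordinates of the first and last window position."""
        return 1 - self.tss_index, self.window_length - self.tss_index

    def motif_positions(self, motif: MotifModel) -> tuple[int, int]:
        """1-based inclusive window positions of the un-jittered motif span."""
        start = motif.offset + self.tss_index
        return start, start + motif.width - 1


def sample_motif(motif: MotifModel, rng: np.random.Generator) -> str:
    """Draw one motif instance, each position independently from its PWM row."""
    cols = [rng.choice(4, p=row) for row in motif.pwm]
    return "".join(ALPHABET[c] for c in cols)


# Codon-position-like composition used for "coding_like" negatives: three
# distinct base-frequency vectors cycled with period 3.
_CODING_PERIODIC = np.array(
    [
        [0.30, 0.17, 0.33, 0.20],  # codon position 1: G/A rich
        [0.32, 0.28, 0.18, 0.22],  # codon position 2: A/T rich
        [0.20, 0.24, 0.28, 0.28],  # codon position 3: G/C rich
    ]
)


def _background_sequence(n: int, bg: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=bg)])


def _coding_like_sequence(n: int, rng: np.random.Generator) -> str:
    codes = np.empty(n, dtype=np.int64)
    for phase in range(3):
        idx = np.arange(phase, n, 3)
        codes[idx] = rng.choice(4, size=idx.size, p=_CODING_PERIODIC[phase])
    return "".join(_BASES[codes])


def generate_corpus(spec: CorpusSpec) -> list[SequenceRecord]:
    """Generate the labeled corpus described by ``spec``.

    Returns promoters first, then non-promoters; deterministic given
    ``spec.seed``.  Each promoter is a background draw with every motif's
    sampled instance overwritten at its (jittered) offset.
    """
    rng = np.random.default_rng(spec.seed)
    bg = np.asarray(spec.background, dtype=np.float64)
    records: list[SequenceRecord] = []
    for i in range(spec.n_promoters):
        seq = list(_background_sequence(spec.window_length, bg, rng))
        for motif in spec.motifs:
            shift = 0
            if motif.offset_jitter:
                shift = int(rng.integers(-motif.offset_jitter, motif.offset_jitter + 1))
            start0 = motif.offset + shift + spec.tss_index - 1  # 0-based
            instance = sample_motif(motif, rng)
            seq[start0 : start0 + motif.width] = instance
        records.append(
            SequenceRecord(
                id=f"prom_{i + 1}",
                sequence="".join(seq),
                label=PROMOTER,
                tss_index=spec.tss_index,
            )
        )
    for i in range(spec.n_nonpromoters):
        if spec.negative_mode == "coding_like":
            seq = _coding_like_sequence(spec.window_length, rng)
        else:
            seq = _background_sequence(spec.window_length, bg, rng)
        records.append(
            SequenceRecord(
                id=f"nonprom_{i + 1}",
                sequence=seq,
                label=NONPROMOTER,
                tss_index=spec.tss_index,
            )
        )
    return records


# ---------------------------------------------------------------------------
# PWM and config file formats

def write_pwm(pwm: np.ndarray, path: str | Path) -> None:
    """Tab-delimited PWM: one row per motif position, columns A, T, G, C."""
    pwm = np.asarray(pwm)
    with open(path, "w") as handle:
        handle.write("# A\tT\tG\tC\n")
        for row in pwm:
            handle.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def read_pwm(path: str | Path) -> np.ndarray:
    """Read a tab-delimited PWM (columns A, T, G, C; '#' lines ignored)."""
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise DataError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-numeric PWM entry") from None
    if not rows:
        raise DataError(f"{path}: empty PWM file")
    pwm = np.array(rows)
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise DataError(f"{path}: PWM rows must sum to 1")
    return pwm


def read_meme_motifs(path: str | Path) -> dict[str, np.ndarray]:
    """Read motifs from MEME minimal motif format.

    MEME letter-probability matrices use alphabet order A, C, G, T; the
    returned PWMs are remapped to this package's A, T, G, C column order.
    """
    motifs: dict[str, np.ndarray] = {}
    name = None
    rows: list[list[float]] = []
    in_matrix = False

    def flush() -> None:
        nonlocal name, rows, in_matrix
        if name is not None and rows:
            acgt = np.array(rows)
            motifs[name] = acgt[:, [0, 3, 2, 1]]  # ACGT -> ATGC
        name, rows, in_matrix = None, [], False

    with open(path) as handle:
        for line in handle:
            stripped = line.strip()
            if stripped.startswith("MOTIF"):
                flush()
                parts = stripped.split()
                if len(parts) < 2:
                    raise DataError(f"{path}: MOTIF line without a name")
                name = parts[1]
            elif stripped.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix and stripped:
                parts = stripped.split()
                if len(parts) == 4:
                    try:
                        rows.append([float(p) for p in parts])
                        continue
                    except ValueError:
                        pass
                in_matrix = False
            elif in_matrix and not stripped:
                in_matrix = False
    flush()
    if not motifs:
        raise DataError(f"{path}: no motifs found (MEME minimal format expected)")
    return motifs


def _parse_motif_token(token: str) -> MotifModel:
    """Parse ``name@offset[~jitter]`` where name is built-in or a PWM file path."""
    body = token.strip()
    jitter = 0
    if "~" in body:
        body, jit = body.rsplit("~", 1)
        try:
            jitter = int(jit)
        except ValueError:
            raise ConfigurationError(f"motif {token!r}: bad jitter {jit!r}") from None
    if "@" not in body:
        raise ConfigurationError(f"motif {token!r}: expected name@offset[~jitter]")
    name, off = body.rsplit("@", 1)
    name = name.strip()
    try:
        offset = int(off)
    except ValueError:
        raise ConfigurationError(f"motif {token!r}: bad offset {off!r}") from None
    if name.lower() in BUILTIN_MOTIFS:
        return BUILTIN_MOTIFS[name.lower()](offset=offset, jitter=jitter)
    if Path(name).exists():
        return MotifModel(Path(name).stem, read_pwm(name), offset, jitter)
    raise ConfigurationError(
        f"motif {name!r}: not a built-in ({', '.join(sorted(BUILTIN_MOTIFS))}) "
        "and no such PWM file"
    )


def read_corpus_config(path: str | Path) -> CorpusSpec:
    """Read a plain-text key/value corpus config.

    Keys: n_promoters, n_nonpromoters, window_length, tss_index, seed,
    background (4 comma-separated probabilities), negative_mode, and one
    ``motif = name@offset[~jitter]`` line per motif.
    """
    kv: dict[str, str] = {}
    motifs: list[MotifModel] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key == "motif":
                motifs.append(_parse_motif_token(value))
            else:
                kv[key] = value
    try:
        spec = CorpusSpec(
            n_promoters=int(kv.get("n_promoters", 0)),
            n_nonpromoters=int(kv.get("n_nonpromoters", 0)),
            window_length=int(kv.get("window_length", 251)),
            tss_index=int(kv.get("tss_index", 201)),
            motifs=tuple(motifs),
            background=tuple(float(x) for x in kv.get("background", "0.25,0.25,0.25,0.25").split(",")),
            seed=int(kv.get("seed", 0)),
            negative_mode=kv.get("negative_mode", "background"),
        )
    except ValueError as exc:
        raise ConfigurationError(f"{path}: {exc}") from None
    return spec
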