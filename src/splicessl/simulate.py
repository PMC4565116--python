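"""Synthetic acceptor-splice-site-like datasets with controllable imbalance.

True acceptor sites sit at the 3' end of an intron and carry an ``AG`` dimer;
the classification task distinguishes them from decoy ``AG`` occurrences.
The generator emulates the essentials of that setting inside a fixed-length
window (default 141 nt, dimer at 1-based positions 61-62):

* positives are drawn from a position weight matrix (PWM) with a
  pyrimidine-rich (C/T) tract upstream of the dimer and an elevated
  consensus just downstream — the canonical acceptor signal;
* negatives are decoys: background composition everywhere except the fixed
  ``AG`` dimer;
* a signal-strength parameter ``s`` in [0, 1] linearly interpolates each
  non-dimer position between background (s=0) and the full acceptor profile
  (s=1), so the difficulty of the task is tunable and s=0 makes the two
  classes identically distributed.

Imbalance is configured as a degree ``d`` (1-to-d: ``d`` negatives per
positive), and :func:`nest_imbalance_series` builds the incremental series
of datasets in which each higher-degree dataset contains every instance of
the lower-degree ones.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import json

import numpy as np

from .sequences import (ALPHABET, DEFAULT_DIMER_START, DEFAULT_WINDOW_LENGTH,
                        NEGATIVE, POSITIVE, SequenceRecord)

#: length of the pyrimidine-rich tract upstream of the dimer
PYRIMIDINE_TRACT = 20
#: C/T probability inside the tract at full signal
PYRIMIDINE_PROB = 0.85
#: consensus profile at the 3 positions downstream of the dimer (exon start),
#: at full signal; rows are probabilities over (A, C, G, T)
DOWNSTREAM_PROFILE = np.array([
    [0.35, 0.15, 0.35, 0.15],   # G/A-rich first exon position
    [0.30, 0.20, 0.30, 0.20],
    [0.30, 0.20, 0.30, 0.20],
])


@dataclass(frozen=True)
class SimulationConfig:
    n_pos: int = 100
    degree: int = 5                      # negatives = degree * n_pos
    window_length: int = DEFAULT_WINDOW_LENGTH
    dimer_start: int = DEFAULT_DIMER_START   # 1-based
    signal: float = 0.6                  # s: 0 = background, 1 = full profile
    background: tuple = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1:
            raise ValueError("n_pos must be >= 1")
        if self.degree < 1:
            raise ValueError("imbalance degree must be >= 1")
        if not (0 <= self.signal <= 1):
            raise ValueError("signal strength must be in [0, 1]")
        if self.dimer_start + 1 > self.window_length or self.dimer_start < 1:
            raise ValueError("dimer must fit inside the window")
        if abs(sum(self.background) - 1) > 1e-9 or min(self.background) < 0:
            raise ValueError("background must be a probability vector")


@dataclass
class AcceptorPWM:
    """Per-position nucleotide probabilities for the positive class.

    The dimer positions are deterministic (A then G); every other row is the
    interpolation ``(1 - s) * background + s * profile``.
    """

    table: np.ndarray          # (L, 4), rows sum to 1
    dimer_start: int           # 1-based

    @classmethod
    def build(cls, config: SimulationConfig) -> "AcceptorPWM":
        L = config.window_length
        bg = np.asarray(config.background, dtype=float)
        profile = np.tile(bg, (L, 1))

        d0 = config.dimer_start - 1        # 0-based index of "A"
        tract = np.array([0.075, PYRIMIDINE_PROB / 2, 0.075,
                          PYRIMIDINE_PROB / 2])
        lo = max(0, d0 - PYRIMIDINE_TRACT)
        profile[lo:d0] = tract
        hi = min(L, d0 + 2 + len(DOWNSTREAM_PROFILE))
        profile[d0 + 2:hi] = DOWNSTREAM_PROFILE[:hi - (d0 + 2)]

        table = (1 - config.signal) * bg + config.signal * profile
        table[d0] = [1.0, 0.0, 0.0, 0.0]       # A
        table[d0 + 1] = [0.0, 0.0, 1.0, 0.0]   # G
        return cls(table=table, dimer_start=config.dimer_start)

    def to_dict(self) -> dict:
        return {"dimer_start": self.dimer_start, "table": self.table.tolist()}


def _draw_sequences(table: np.ndarray, n: int,
                    rng: np.random.Generator) -> list[str]:
    L = table.shape[0]
    cum = np.cumsum(table, axis=1)
    cum[:, -1] = 1.0
    u = rng.random((n, L))
    codes = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    nts = np.array(list(ALPHABET))
    return ["".join(row) for row in nts[codes]]


def simulate_records(config: SimulationConfig) -> list[SequenceRecord]:
    """Generate ``n_pos`` positives followed by ``degree * n_pos`` decoys."""
    rng = np.random.default_rng(config.seed)
    pwm = AcceptorPWM.build(config)

    bg_table = np.tile(np.asarray(config.background, dtype=float),
                       (config.window_length, 1))
    d0 = config.dimer_start - 1
    bg_table[d0] = [1.0, 0.0, 0.0, 0.0]
    bg_table[d0 + 1] = [0.0, 0.0, 1.0, 0.0]

    records = [SequenceRecord(f"pos_{i:06d}", seq, POSITIVE)
               for i, seq in enumerate(
                   _draw_sequences(pwm.table, config.n_pos, rng))]
    n_neg = config.degree * config.n_pos
    records += [SequenceRecord(f"neg_{i:06d}", seq, NEGATIVE)
                for i, seq in enumerate(_draw_sequences(bg_table, n_neg, rng))]
    return records


def nest_imbalance_series(base: list[SequenceRecord], degrees: list[int],
                          seed: int = 0) -> dict[int, list[SequenceRecord]]:
    """Build nested datasets: one per degree, sharing positives, with
    negative sets nested by inclusion across increasing degrees.

    The dataset at degree ``d`` holds every positive plus exactly
    ``d * n_pos`` negatives, and contains all instances of every
    lower-degree dataset.
    """
    rng = np.random.default_rng(seed)
    pos = [r for r in base if r.label == POSITIVE]
    neg = [r for r in base if r.label == NEGATIVE]
    if not pos:
        raise ValueError("base dataset has no positives")
    degrees = sorted(set(int(d) for d in degrees))
    largest_need = degrees[-1] * len(pos)
    if largest_need > len(neg):
        raise ValueError(
            f"insufficient negatives for degree 1-to-{degrees[-1]}: "
            f"need {largest_need}, have {len(neg)}")
    order = rng.permutation(len(neg))
    out = {}
    for d in degrees:
        take = order[:d * len(pos)]
        out[d] = pos + [neg[i] for i in take]
    return out


def write_sidecar(path, config: SimulationConfig) -> None:
    """JSON sidecar recording the config and PWM for reproducibility."""
    doc = {"config": asdict(config),
           "pwm": AcceptorPWM.build(config).to_dict()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
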