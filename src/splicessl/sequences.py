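"""Fixed-length sequence windows and their two categorical feature views.

Every classifier in this package sees a DNA window of fixed length *L*
(default 141 nt, with the acceptor ``AG`` dimer at 1-based positions 61-62)
through one of two static views:

* **view1** — nucleotide/position: one categorical feature per position,
  ``L`` features with 4 categories each;
* **view2** — 3-mer/position: one categorical feature per overlapping
  trimer start, ``L - 2`` features with 64 categories each.

The *combined* view is the concatenation ``view1 || view2`` (280 features
for L=141).  Views are deterministic functions of the sequence and view1 is
invertible back to it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

POSITIVE = 1
NEGATIVE = 0
UNLABELED = -1

LABEL_NAMES = {POSITIVE: "positive", NEGATIVE: "negative", UNLABELED: "unlabeled"}

ALPHABET = "ACGT"
_NT_CODE = {c: i for i, c in enumerate(ALPHABET)}

DEFAULT_WINDOW_LENGTH = 141
DEFAULT_DIMER_START = 61  # 1-based; "AG" occupies positions 61-62

#: header-token -> label rule applied to the first whitespace-separated token
#: after the record id (configurable via ``label_rule`` / ``label_regex``)
DEFAULT_LABEL_RULE = {
    "+1": POSITIVE,
    "pos": POSITIVE,
    "positive": POSITIVE,
    "-1": NEGATIVE,
    "neg": NEGATIVE,
    "negative": NEGATIVE,
}


class SequenceValidationError(ValueError):
    """A record violates the window-length or alphabet invariants."""


@dataclass(frozen=True)
class SequenceRecord:
    """A fixed-length DNA window with an optional class label."""

    id: str
    sequence: str
    label: int = UNLABELED

    def validate(self, window_length: int = DEFAULT_WINDOW_LENGTH,
                 iupac_policy: str = "reject") -> None:
        # Ambiguity codes are rejected: the Naïve Bayes category sets are
        # fixed at 4 nucleotides / 64 trimers, so IUPAC letters have no slot.
        if iupac_policy != "reject":
            raise ValueError(f"unsupported iupac policy {iupac_policy!r}")
        if len(self.sequence) != window_length:
            raise SequenceValidationError(
                f"record {self.id!r}: length {len(self.sequence)} != "
                f"configured window length {window_length}")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise SequenceValidationError(
                f"record {self.id!r}: non-ACGT character "
                f"{self.sequence[pos]!r} at position {pos + 1}")


@dataclass(frozen=True)
class ViewSpec:
    """Geometry of the two static feature views for a window length."""

    window_length: int = DEFAULT_WINDOW_LENGTH
    dimer_start: int = DEFAULT_DIMER_START  # 1-based start of the "AG" dimer

    def __post_init__(self) -> None:
        if self.window_length < 3:
            raise ValueError("window length must be >= 3 for the trimer view")
        if not (1 <= self.dimer_start and self.dimer_start + 1 <= self.window_length):
            raise ValueError("dimer must fit inside the window")

    @property
    def n_view1(self) -> int:
        return self.window_length

    @property
    def n_view2(self) -> int:
        return self.window_length - 2

    def n_categories(self, view: str) -> np.ndarray:
        """Per-feature category-set sizes for a view tag."""
        if view == "view1":
            return np.full(self.n_view1, 4, dtype=np.int64)
        if view == "view2":
            return np.full(self.n_view2, 64, dtype=np.int64)
        if view == "combined":
            return np.concatenate([self.n_categories("view1"),
                                   self.n_categories("view2")])
        raise ValueError(f"unknown view tag {view!r}")


class EncodingError(ValueError):
    pass


def encode_nucleotide_view(record: SequenceRecord) -> np.ndarray:
    """Encode a record as its nucleotide/position vector (codes 0..3)."""
    try:
        return np.fromiter((_NT_CODE[c] for c in record.sequence),
                           dtype=np.int8, count=len(record.sequence))
    except KeyError as exc:
        pos = record.sequence.index(exc.args[0]) + 1
        raise EncodingError(
            f"record {record.id!r}: invalid character {exc.args[0]!r} "
            f"at position {pos}") from None


def encode_trimer_view(record: SequenceRecord) -> np.ndarray:
    """Encode a record as its overlapping 3-mer/position vector (codes 0..63)."""
    if len(record.sequence) < 3:
        raise SequenceValidationError(
            f"record {record.id!r}: length {len(record.sequence)} < 3")
    v1 = encode_nucleotide_view(record).astype(np.int16)
    return (16 * v1[:-2] + 4 * v1[1:-1] + v1[2:]).astype(np.int8)


def decode_nucleotide_view(codes: Sequence[int]) -> str:
    """Inverse of :func:`encode_nucleotide_view`."""
    return "".join(ALPHABET[int(c)] for c in codes)


def trimer_name(code: int) -> str:
    return ALPHABET[code // 16] + ALPHABET[(code // 4) % 4] + ALPHABET[code % 4]


@dataclass
class EncodedDataset:
    """A column-oriented batch of encoded instances.

    Rows are instances in input order; ``view1`` is (n, L) and ``view2`` is
    (n, L-2), both integer category codes.  Single rows are exposed as
    :class:`EncodedInstance` for interface parity with per-instance code.
    """

    spec: ViewSpec
    ids: list[str]
    labels: np.ndarray  # int8: POSITIVE / NEGATIVE / UNLABELED
    view1: np.ndarray
    view2: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def matrix(self, view: str) -> np.ndarray:
        if view == "view1":
            return self.view1
        if view == "view2":
            return self.view2
        if view == "combined":
            return np.concatenate([self.view1, self.view2.astype(np.int8)], axis=1)
        raise ValueError(f"unknown view tag {view!r}")

    def subset(self, idx: Iterable[int]) -> "EncodedDataset":
        idx = np.asarray(list(idx), dtype=np.intp)
        return EncodedDataset(self.spec, [self.ids[i] for i in idx],
                              self.labels[idx], self.view1[idx], self.view2[idx])

    def instance(self, i: int) -> "EncodedInstance":
        return EncodedInstance(self.ids[i], int(self.labels[i]),
                               self.view1[i], self.view2[i])


@dataclass(frozen=True)
class EncodedInstance:
    id: str
    label: int
    view1: np.ndarray
    view2: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.view1, self.view2])

    @property
    def sequence(self) -> str:
        return decode_nucleotide_view(self.view1)


def make_label_rule(regex: str | None = None) -> dict | None:
    """Build a header-token label rule; ``regex`` overrides the default map."""
    if regex is None:
        return dict(DEFAULT_LABEL_RULE)
    pat = re.compile(regex)

    class _RegexRule(dict):
        def get(self, token, default=None):  # type: ignore[override]
            m = pat.search(token)
            if not m:
                return default
            return DEFAULT_LABEL_RULE.get(m.group(0).lower(), default)

    return _RegexRule()


def read_fasta(path, window_length: int = DEFAULT_WINDOW_LENGTH,
               label_rule: dict | None = None,
               iupac_policy: str = "reject") -> list[SequenceRecord]:
    """Read fixed-length windows from a FASTA file.

    The label is taken from the first whitespace-separated header token after
    the id, looked up in ``label_rule`` (case-insensitively); records with no
    matching token are unlabeled.  Every sequence must have the configured
    window length.
    """
    if label_rule is None:
        label_rule = DEFAULT_LABEL_RULE
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        label = UNLABELED
        for tok in tokens[1:]:
            hit = label_rule.get(tok.lower())
            if hit is not None:
                label = hit
                break
        sr = SequenceRecord(rec.id, str(rec.seq).upper(), label)
        sr.validate(window_length, iupac_policy)
        records.append(sr)
    return records


def write_fasta(path, records: Iterable[SequenceRecord]) -> None:
    """Write records with labels encoded as a header token (pos/neg/unk)."""
    token = {POSITIVE: "pos", NEGATIVE: "neg", UNLABELED: "unk"}
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {token[rec.label]}\n{rec.sequence}\n")


def encode_dataset(records: Sequence[SequenceRecord],
                   spec: ViewSpec | None = None,
                   iupac_policy: str = "reject") -> EncodedDataset:
    """Encode records into both views, preserving order and labels."""
    if spec is None:
        spec = ViewSpec()
    n = len(records)
    view1 = np.empty((n, spec.n_view1), dtype=np.int8)
    view2 = np.empty((n, spec.n_view2), dtype=np.int8)
    labels = np.empty(n, dtype=np.int8)
    ids = []
    for i, rec in enumerate(records):
        rec.validate(spec.window_length, iupac_policy)
        view1[i] = encode_nucleotide_view(rec)
        view2[i] = encode_trimer_view(rec)
        labels[i] = rec.label
        ids.append(rec.id)
    return EncodedDataset(spec, ids, labels, view1, view2)


def export_tsv(path, data: EncodedDataset) -> None:
    """Debug export: id, label, then tab-separated feature values."""
    with open(path, "w") as fh:
        for i in range(len(data)):
            row = data.instance(i)
            feats = [ALPHABET[c] for c in row.view1]
            feats += [trimer_name(c) for c in row.view2]
            fh.write("\t".join([row.id, LABEL_NAMES[row.label], *feats]) + "\n")
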