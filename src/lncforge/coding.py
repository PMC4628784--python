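"""Coding-potential scoring for assembled transcripts.

The score is a logistic combination of three sequence features, mirroring
the classical coding-potential assessment approach:

* length of the longest ATG-initiated, stop-terminated open reading frame
  (stop codon included, forward strand of the spliced transcript only);
* the Fickett TESTCODE statistic, an 8-parameter position/composition score
  computed from the classical published lookup tables;
* the hexamer usage bias, the mean log-ratio of in-frame hexamer
  frequencies between a coding and a non-coding training corpus.

Transcripts scoring below the decision threshold (default 0.364) are called
non-coding.  The logistic weights are fit on user-supplied training corpora
with an L2-regularized maximum-likelihood fit, which keeps the weights
finite when the corpora are linearly separable.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .intervals import ValidationError

DEFAULT_THRESHOLD = 0.364
START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
ALPHABET = frozenset("ACGTN")

ALL_HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]

# Fickett TESTCODE lookup tables: 10 probability intervals per base for the
# position parameter (base periodicity) and the content parameter (base
# fraction), each with its own weight.
_POSITION_PROB = {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.49, 0.37, 0.38, 0.30, 0.23, 0.20],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.52, 0.41, 0.31, 0.17],
    "T": [0.51, 0.60, 0.69, 0.64, 0.53, 0.54, 0.44, 0.40, 0.31, 0.33],
}
_POSITION_WEIGHT = {"A": 0.22, "C": 0.23, "G": 0.24, "T": 0.18}
# value >= 1.9 -> first entry, then 0.1-wide bins down to < 1.1 -> last entry
_POSITION_EDGES = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1]

_CONTENT_PROB = {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19],
    "C": [0.50, 0.63, 0.59, 0.50, 0.41, 0.30, 0.33, 0.29, 0.24, 0.18],
    "G": [0.21, 0.40, 0.47, 0.46, 0.52, 0.58, 0.57, 0.52, 0.44, 0.11],
    "T": [0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.34, 0.20, 0.11, 0.33],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
# fraction >= 0.33 -> first entry, then 0.02-wide bins down to < 0.17 -> last
_CONTENT_EDGES = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17]


@dataclass
class CodingFeatures:
    """Per-transcript features feeding the logistic coding-potential model."""

    orf_length: int
    fickett_score: float
    hexamer_bias: float
    coding_score: float | None = None


@dataclass
class CodingPotentialModel:
    """Trained hexamer table, logistic weights and decision threshold."""

    hexamer_logratio: dict
    intercept: float
    coefficients: tuple  # (orf_length, fickett_score, hexamer_bias)
    feature_means: tuple
    feature_scales: tuple
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValidationError(f"threshold {self.threshold} outside (0,1)")
        missing = len(ALL_HEXAMERS) - len(self.hexamer_logratio)
        if missing:
            raise ValidationError(f"hexamer table incomplete: {missing} hexamers missing")

    def score(self, features: CodingFeatures) -> float:
        x = np.array(
            [features.orf_length, features.fickett_score, features.hexamer_bias],
            dtype=float,
        )
        z = (x - np.array(self.feature_means)) / np.array(self.feature_scales)
        eta = self.intercept + float(np.dot(self.coefficients, z))
        return 1.0 / (1.0 + math.exp(-eta))

    def to_json(self, path) -> None:
        payload = {
            "hexamer_logratio": self.hexamer_logratio,
            "intercept": self.intercept,
            "coefficients": list(self.coefficients),
            "feature_means": list(self.feature_means),
            "feature_scales": list(self.feature_scales),
            "threshold": self.threshold,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle)

    @classmethod
    def from_json(cls, path) -> "CodingPotentialModel":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(
            hexamer_logratio=payload["hexamer_logratio"],
            intercept=payload["intercept"],
            coefficients=tuple(payload["coefficients"]),
            feature_means=tuple(payload["feature_means"]),
            feature_scales=tuple(payload["feature_scales"]),
            threshold=payload["threshold"],
        )


# ---------------------------------------------------------------------------
# Features

def longest_orf_span(sequence: str) -> tuple[int, int]:
    """(length, start) of the longest ATG..stop ORF across the three forward
    frames; (0, -1) when none exists.  Ties broken by leftmost start."""
    seq = sequence.upper()
    bad = set(seq) - ALPHABET
    if bad:
        raise ValidationError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    best_len, best_start = 0, -1
    for frame in range(3):
        open_start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if open_start is None:
                if codon == START_CODON:
                    open_start = i
            elif codon in STOP_CODONS:
                length = i + 3 - open_start
                if length > best_len or (length == best_len and open_start < best_start):
                    best_len, best_start = length, open_start
                open_start = None
    return best_len, best_start


def find_longest_orf(sequence: str) -> tuple[int, str]:
    """Longest ATG..stop ORF across the three forward frames.

    Returns (length in nt including the stop codon, ORF subsequence);
    (0, "") when no complete ORF exists.  Ties are broken by the leftmost
    start position.
    """
    best_len, best_start = longest_orf_span(sequence)
    if best_len == 0:
        return 0, ""
    return best_len, sequence.upper()[best_start:best_start + best_len]


def _lookup(value: float, edges, probs) -> float:
    for i, edge in enumerate(edges):
        if value >= edge:
            return probs[i]
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence (length >= 2)."""
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValidationError("Fickett score requires a sequence of length >= 2")
    phase_counts = {b: [0, 0, 0] for b in "ACGT"}
    totals = {b: 0 for b in "ACGT"}
    n_acgt = 0
    for i, base in enumerate(seq):
        if base in phase_counts:
            phase_counts[base][i % 3] += 1
            totals[base] += 1
            n_acgt += 1
    score = 0.0
    for base in "ACGT":
        counts = phase_counts[base]
        position_value = max(counts) / (min(counts) + 1.0)
        score += _lookup(position_value, _POSITION_EDGES, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        content = totals[base] / n_acgt if n_acgt else 0.0
        score += _lookup(content, _CONTENT_EDGES, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


def hexamer_bias(orf_subsequence: str, hexamer_logratio) -> float:
    """Mean hexamer log-ratio over frame-0 hexamers stepping by 3.

    Returns 0.0 for inputs shorter than one hexamer.
    """
    seq = orf_subsequence.upper()
    if len(seq) < 6:
        return 0.0
    values = []
    for i in range(0, len(seq) - 5, 3):
        hexamer = seq[i:i + 6]
        if hexamer in hexamer_logratio:
            values.append(hexamer_logratio[hexamer])
    if not values:
        return 0.0
    return float(np.mean(values))


def compute_features(sequence: str, hexamer_logratio) -> CodingFeatures:
    orf_len, orf_seq = find_longest_orf(sequence)
    return CodingFeatures(
        orf_length=orf_len,
        fickett_score=fickett_score(sequence),
        hexamer_bias=hexamer_bias(orf_seq, hexamer_logratio),
    )


# ---------------------------------------------------------------------------
# Training and classification

def _hexamer_frequencies(sequences) -> dict:
    counts = dict.fromkeys(ALL_HEXAMERS, 1.0)  # +1 pseudocount
    for seq in sequences:
        seq = seq.upper()
        for i in range(0, len(seq) - 5, 3):
            hexamer = seq[i:i + 6]
            if hexamer in counts:
                counts[hexamer] += 1.0
    total = sum(counts.values())
    return {h: c / total for h, c in counts.items()}


def build_hexamer_table(coding_sequences, noncoding_sequences) -> dict:
    """log(f_coding / f_noncoding) for every hexamer, pseudocount-smoothed."""
    f_cod = _hexamer_frequencies(coding_sequences)
    f_non = _hexamer_frequencies(noncoding_sequences)
    return {h: math.log(f_cod[h] / f_non[h]) for h in ALL_HEXAMERS}


def train_coding_model(
    coding_sequences,
    noncoding_sequences,
    threshold: float = DEFAULT_THRESHOLD,
    min_sequences: int = 50,
) -> CodingPotentialModel:
    """Train the hexamer table and logistic weights from two corpora.

    Each argument is either a list of sequences or a FASTA path.  At least
    ``min_sequences`` sequences per class are required.
    """
    from .io import read_fasta

    if isinstance(coding_sequences, (str, bytes)) or hasattr(coding_sequences, "__fspath__"):
        coding_sequences = list(read_fasta(coding_sequences).values())
    if isinstance(noncoding_sequences, (str, bytes)) or hasattr(noncoding_sequences, "__fspath__"):
        noncoding_sequences = list(read_fasta(noncoding_sequences).values())
    coding_sequences = list(coding_sequences)
    noncoding_sequences = list(noncoding_sequences)
    if len(coding_sequences) < min_sequences or len(noncoding_sequences) < min_sequences:
        raise ValidationError(
            f"training requires >= {min_sequences} sequences per class, got "
            f"{len(coding_sequences)} coding / {len(noncoding_sequences)} non-coding"
        )
    table = build_hexamer_table(coding_sequences, noncoding_sequences)
    rows, labels = [], []
    for label, seqs in ((1, coding_sequences), (0, noncoding_sequences)):
        for seq in seqs:
            feats = compute_features(seq, table)
            rows.append([feats.orf_length, feats.fickett_score, feats.hexamer_bias])
            labels.append(label)
    X = np.array(rows, dtype=float)
    y = np.array(labels)
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite training feature encountered")
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    Z = (X - means) / scales
    clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
    clf.fit(Z, y)
    return CodingPotentialModel(
        hexamer_logratio=table,
        intercept=float(clf.intercept_[0]),
        coefficients=tuple(float(c) for c in clf.coef_[0]),
        feature_means=tuple(means),
        feature_scales=tuple(scales),
        threshold=threshold,
    )


def classify_coding(features: CodingFeatures, model: CodingPotentialModel) -> str:
    """'noncoding' when score < threshold, else 'coding' (boundary -> coding)."""
    score = features.coding_score
    if score is None:
        score = model.score(features)
    return "coding" if score >= model.threshold else "noncoding"


def score_sequences(sequences, model: CodingPotentialModel) -> dict:
    """Score a name -> sequence mapping; returns name -> CodingFeatures."""
    out = {}
    for name, seq in sequences.items():
        feats = compute_features(seq, model.hexamer_logratio)
        feats.coding_score = model.score(feats)
        out[name] = feats
    return out
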