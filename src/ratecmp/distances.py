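"""Pairwise divergence estimators.

Two estimators feed the rate comparison:

* **K2P** (Kimura two-parameter) nucleotide distance, correcting separately
  for the transition proportion ``P`` and the transversion proportion ``Q``:
  ``d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]``.  The correction is
  undefined (saturation) when ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``.

* **NG86** (Nei–Gojobori) synonymous/nonsynonymous counting.  Each codon
  contributes fractional synonymous and nonsynonymous *site* counts (per
  position, the fraction of valid single-nucleotide changes that are
  synonymous; changes that create stop codons are excluded from both
  numerator and denominator).  *Differences* between codons differing at
  ``k`` positions are averaged over all ``k!`` substitution pathways that
  avoid stop codons, each weighted equally.  ``pS = S_diff / S_sites``;
  ``dS`` applies the Jukes–Cantor-style correction
  ``-(3/4) * ln(1 - 4/3 * p)``, undefined when ``p >= 3/4``.

Undefined (saturated) values propagate as ``NaN`` plus an explicit flag,
never as numeric sentinels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Literal

import numpy as np
from Bio.Data import CodonTable

from .alignio import CodonAlignment

__all__ = [
    "K2PResult",
    "NGResult",
    "DistanceMatrix",
    "k2p_distance",
    "ng86_pair",
    "pairwise_matrix",
    "jukes_cantor_correction",
    "synonymous_site_fraction",
]

NUCS = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


# ---------------------------------------------------------------------------
# K2P


@dataclass(frozen=True)
class K2PResult:
    """Kimura two-parameter distance between two sequences.

    ``d`` is ``NaN`` with ``saturated=True`` when the log correction is
    outside its domain.
    """

    P: float
    Q: float
    d: float
    n_sites: int
    saturated: bool = False

    @property
    def defined(self) -> bool:
        return not self.saturated and math.isfinite(self.d)

    @property
    def p_distance(self) -> float:
        return self.P + self.Q


def k2p_distance(seqA: str, seqB: str) -> K2PResult:
    """K2P distance with pairwise deletion of gap/ambiguous positions.

    Positions where either sequence is not a plain ``A/C/G/T`` are excluded.
    Raises ``ValueError`` on unequal lengths or zero comparable sites.
    """
    if len(seqA) != len(seqB):
        raise ValueError(f"unequal sequence lengths {len(seqA)} != {len(seqB)}")
    n = ts = tv = 0
    for a, b in zip(seqA.upper(), seqB.upper()):
        if a not in NUCS or b not in NUCS:
            continue
        n += 1
        if a != b:
            if _is_transition(a, b):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites (all gapped or ambiguous)")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(P, Q, float("nan"), n, saturated=True)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(P, Q, d, n, saturated=False)


# ---------------------------------------------------------------------------
# NG86

_STANDARD = CodonTable.unambiguous_dna_by_id[1]


@lru_cache(maxsize=8)
def _code(code_id: int):
    """(aa_map, stop_set, sense_codons) for an NCBI genetic code id."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    aa = dict(table.forward_table)
    stops = frozenset(table.stop_codons)
    sense = tuple(sorted(aa))
    return aa, stops, sense


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str, code_id: int = 1) -> float:
    """Synonymous site count of a sense codon (in sites, range 0..3).

    Per position, the fraction of single-nucleotide changes that are
    synonymous among the changes not creating a stop codon.
    """
    aa, stops, _ = _code(code_id)
    if codon in stops or codon not in aa:
        raise ValueError(f"not a sense codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in stops:
                continue
            valid += 1
            if aa[mutant] == aa[codon]:
                syn += 1
        if valid:
            s += syn / valid
    return s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str, code_id: int = 1):
    """Mean (synonymous, nonsynonymous) difference counts for a codon pair.

    Averages over all substitution pathways between ``c1`` and ``c2`` that
    avoid stop codons, each pathway weighted equally.  Returns ``None`` when
    every pathway passes through a stop codon.
    """
    aa, stops, _ = _code(code_id)
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot = non_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops:
                ok = False
                break
            if aa[nxt] == aa[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            syn_tot += syn
            non_tot += non
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_tot / n_paths, non_tot / n_paths


def jukes_cantor_correction(p: float) -> float:
    """``-(3/4) ln(1 - 4p/3)``; ``NaN`` when ``p >= 3/4`` (saturation)."""
    if not math.isfinite(p) or p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class NGResult:
    """NG86 site and difference counts for a pair of codon sequences."""

    S_sites: float
    N_sites: float
    S_diff: float
    N_diff: float
    n_codons: int
    n_skipped: int

    @property
    def pS(self) -> float:
        return self.S_diff / self.S_sites if self.S_sites > 0 else float("nan")

    @property
    def pN(self) -> float:
        return self.N_diff / self.N_sites if self.N_sites > 0 else float("nan")

    @property
    def dS(self) -> float:
        return jukes_cantor_correction(self.pS)

    @property
    def dN(self) -> float:
        return jukes_cantor_correction(self.pN)


def ng86_pair(codonsA: str, codonsB: str, code_id: int = 1) -> NGResult:
    """NG86 counts between two equal-length, codon-framed sequences.

    Codons containing gaps or ambiguous bases in either sequence, codons
    that are stops in either sequence, and codon pairs whose every pathway
    crosses a stop are skipped (counted in ``n_skipped``).  Site totals are
    the average of the two sequences' per-codon site counts.
    """
    if len(codonsA) != len(codonsB):
        raise ValueError("unequal sequence lengths")
    if len(codonsA) % 3:
        raise ValueError(f"length {len(codonsA)} is not a multiple of 3")
    aa, stops, _ = _code(code_id)
    S = N = Sd = Nd = 0.0
    used = skipped = 0
    for i in range(0, len(codonsA), 3):
        c1, c2 = codonsA[i : i + 3].upper(), codonsB[i : i + 3].upper()
        if any(ch not in NUCS for ch in c1 + c2) or c1 in stops or c2 in stops:
            skipped += 1
            continue
        diffs = _pair_differences(c1, c2, code_id)
        if diffs is None:
            skipped += 1
            continue
        s1 = synonymous_site_fraction(c1, code_id)
        s2 = synonymous_site_fraction(c2, code_id)
        S += 0.5 * (s1 + s2)
        N += 3.0 - 0.5 * (s1 + s2)
        Sd += diffs[0]
        Nd += diffs[1]
        used += 1
    if used == 0:
        raise ValueError("no comparable codons")
    return NGResult(S, N, Sd, Nd, used, skipped)


# ---------------------------------------------------------------------------
# Distance matrices

Metric = Literal["d", "pN", "pS", "dN", "dS"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with explicit saturation flags.

    ``values[i, j]`` is ``NaN`` where the estimator is undefined; the
    boolean ``saturated`` mask marks those entries.
    """

    labels: list[str]
    values: np.ndarray
    saturated: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.saturated = np.asarray(self.saturated, dtype=bool)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def is_defined(self, a: str, b: str) -> bool:
        i, j = self.labels.index(a), self.labels.index(b)
        return not self.saturated[i, j] and np.isfinite(self.values[i, j])

    @property
    def any_undefined(self) -> bool:
        off = ~np.eye(len(self.labels), dtype=bool)
        return bool(np.any(self.saturated[off]) or np.any(~np.isfinite(self.values[off])))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_phylip(self, path) -> None:
        """PHYLIP square matrix; undefined entries written as -1.0."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = [
                    f"{v:.6f}" if np.isfinite(v) else "-1.000000"
                    for v in self.values[i]
                ]
                fh.write(f"{lab:<10s} " + " ".join(row) + "\n")

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", na_rep="NA")


def _metric_value(seqA: str, seqB: str, metric: Metric) -> tuple[float, bool]:
    """(value, saturated) for one record pair under *metric*."""
    if metric == "d":
        r = k2p_distance(seqA, seqB)
        return r.d, r.saturated
    ng = ng86_pair(seqA, seqB)
    v = getattr(ng, metric)
    return v, not math.isfinite(v)


def pairwise_matrix(
    aln: CodonAlignment,
    metric: Metric = "d",
    collapse: Literal["record", "species-mean"] = "record",
) -> DistanceMatrix:
    """Pairwise distances over records, or species-averaged over paralogs.

    With ``collapse="species-mean"`` the entry for a species pair is the
    arithmetic mean of the defined record-pair distances (paralog rule);
    it is undefined only when every contributing record pair is undefined.
    """
    if aln.n_records < 2:
        raise ValueError("need at least 2 records")
    rec_labels = [rid for rid, _, _ in aln.records]
    seqs = [seq for _, _, seq in aln.records]
    n = len(seqs)
    vals = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            v, s = _metric_value(seqs[i], seqs[j], metric)
            vals[i, j] = vals[j, i] = v
            sat[i, j] = sat[j, i] = s
    if collapse == "record":
        return DistanceMatrix(rec_labels, vals, sat)

    species = aln.species
    idx = {sp: [k for k, (_, s, _) in enumerate(aln.records) if s == sp] for sp in species}
    m = len(species)
    svals = np.zeros((m, m))
    ssat = np.zeros((m, m), dtype=bool)
    for a in range(m):
        for b in range(a + 1, m):
            pair_vals = [
                vals[i, j]
                for i in idx[species[a]]
                for j in idx[species[b]]
                if not sat[i, j] and np.isfinite(vals[i, j])
            ]
            if pair_vals:
                svals[a, b] = svals[b, a] = float(np.mean(pair_vals))
            else:
                svals[a, b] = svals[b, a] = float("nan")
                ssat[a, b] = ssat[b, a] = True
    return DistanceMatrix(list(species), svals, ssat)
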