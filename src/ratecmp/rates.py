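"""Per-locus, per-species evolutionary-rate estimation.

Two tracks turn a codon alignment into lineage-specific rates for a pair of
focal species A and B:

* **outgroup** — the relative-rate decomposition.  With an outgroup O that
  diverged before the A–B split, the pairwise distance splits into the two
  lineage contributions since the split::

      d_A = (d_AB + d_AO - d_BO) / 2
      d_B = (d_AB + d_BO - d_AO) / 2

  which conserves ``d_A + d_B = d_AB`` exactly.  Any estimator of pairwise
  divergence can be decomposed this way (K2P ``d``, NG86 ``pN``/``pS`` or
  their corrected ``dN``/``dS``).

* **ml** — maximum-likelihood branch lengths on the locus topology under
  K80; the rate of a species is the length of its terminal branch (tip to
  nearest node), which does not require the distant outgroup and is less
  exposed to saturation.

Species with several paralogous records are handled by arithmetic
averaging: pairwise distances are averaged over paralog pairs before
decomposition (equivalent, by linearity of the decomposition, to averaging
the decomposed rates).  Negative decomposed rates are retained but flagged;
saturated inputs yield undefined, flagged outputs — never silent drops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignio import CodonAlignment
from .distances import DistanceMatrix, k2p_distance, ng86_pair
from .phylo import k2p_matrix_from_codes, encode_alignment, ml_branch_lengths, nj_tree

__all__ = [
    "LocusRates",
    "outgroup_decompose",
    "paralog_average",
    "species_distance_matrices",
    "locus_rates_outgroup",
    "locus_rates_ml",
    "build_rate_table",
    "rates_to_long_table",
]

OK = "ok"
NEGATIVE = "negative"
UNDEFINED = "undefined"

ESTIMATORS = ("d", "pN", "pS", "dN", "dS")


@dataclass
class LocusRates:
    """Per-species rate estimates for one locus under one method.

    ``values[(species, estimator)]`` maps to the rate; ``flags`` carries
    ``"ok"``, ``"negative"`` or ``"undefined"`` per value.
    """

    locus_id: str
    method: str
    values: dict[tuple[str, str], float] = field(default_factory=dict)
    flags: dict[tuple[str, str], str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def get(self, species: str, estimator: str) -> tuple[float, str]:
        key = (species, estimator)
        return self.values.get(key, float("nan")), self.flags.get(key, UNDEFINED)


def outgroup_decompose(
    d_AB: float, d_AO: float, d_BO: float
) -> tuple[tuple[float, str], tuple[float, str]]:
    """Split a pairwise distance into lineage-specific rates via an outgroup.

    Returns ``((d_A, flag_A), (d_B, flag_B))``.  Undefined inputs (NaN)
    yield undefined outputs; negative outputs are kept but flagged.
    """
    if not all(math.isfinite(v) for v in (d_AB, d_AO, d_BO)):
        nan = float("nan")
        return (nan, UNDEFINED), (nan, UNDEFINED)
    d_A = (d_AB + d_AO - d_BO) / 2.0
    d_B = (d_AB + d_BO - d_AO) / 2.0
    return (
        (d_A, NEGATIVE if d_A < 0 else OK),
        (d_B, NEGATIVE if d_B < 0 else OK),
    )


def paralog_average(values: Iterable[float]) -> tuple[float, str]:
    """Arithmetic mean of the defined values among paralog estimates.

    Returns ``(mean, flag)``; the flag is ``"undefined"`` when no value is
    defined, ``"negative"`` when any contributing value is negative.
    """
    defined = [v for v in values if v is not None and math.isfinite(v)]
    if not defined:
        return float("nan"), UNDEFINED
    mean = float(np.mean(defined))
    flag = NEGATIVE if any(v < 0 for v in defined) else OK
    return mean, flag


def species_distance_matrices(
    aln: CodonAlignment, estimators: Sequence[str] = ("d", "pN", "pS")
) -> dict[str, DistanceMatrix]:
    """Species-collapsed pairwise matrices, one per estimator.

    K2P and NG86 are each computed once per record pair; paralog pairs are
    averaged (defined values only) into the species-level entry.
    """
    for est in estimators:
        if est not in ESTIMATORS:
            raise ValueError(f"unknown estimator {est!r}")
    species = aln.species
    idx = {
        sp: [k for k, (_, s, _) in enumerate(aln.records) if s == sp] for sp in species
    }
    seqs = [seq for _, _, seq in aln.records]
    n = len(seqs)
    need_ng = any(e != "d" for e in estimators)
    rec_vals: dict[str, np.ndarray] = {
        est: np.full((n, n), np.nan) for est in estimators
    }
    for i in range(n):
        for j in range(i + 1, n):
            if "d" in estimators:
                r = k2p_distance(seqs[i], seqs[j])
                rec_vals["d"][i, j] = rec_vals["d"][j, i] = r.d
            if need_ng:
                ng = ng86_pair(seqs[i], seqs[j])
                for est in estimators:
                    if est == "d":
                        continue
                    v = getattr(ng, est)
                    rec_vals[est][i, j] = rec_vals[est][j, i] = v
    out: dict[str, DistanceMatrix] = {}
    m = len(species)
    for est in estimators:
        vals = np.zeros((m, m))
        sat = np.zeros((m, m), dtype=bool)
        for a in range(m):
            for b in range(a + 1, m):
                pv = [
                    rec_vals[est][i, j]
                    for i in idx[species[a]]
                    for j in idx[species[b]]
                    if math.isfinite(rec_vals[est][i, j])
                ]
                if pv:
                    vals[a, b] = vals[b, a] = float(np.mean(pv))
                else:
                    vals[a, b] = vals[b, a] = float("nan")
                    sat[a, b] = sat[b, a] = True
        out[est] = DistanceMatrix(list(species), vals, sat)
    return out


def locus_rates_outgroup(
    aln: CodonAlignment,
    speciesA: str,
    speciesB: str,
    outgroup: str,
    estimators: Sequence[str] = ("d", "pN", "pS"),
) -> LocusRates:
    """Outgroup-decomposed rates of two focal species at one locus.

    Species-collapsed pairwise values (paralogs averaged) feed the
    decomposition per estimator; a saturated pairwise value marks that
    estimator undefined for both species at this locus.
    """
    present = set(aln.species)
    missing = {speciesA, speciesB, outgroup} - present
    if missing:
        raise ValueError(f"{aln.locus_id}: species not in alignment: {sorted(missing)}")
    sub = aln.subset([speciesA, speciesB, outgroup])
    mats = species_distance_matrices(sub, estimators)
    lr = LocusRates(aln.locus_id, "outgroup")
    for est, dm in mats.items():
        d_ab = dm.get(speciesA, speciesB)
        d_ao = dm.get(speciesA, outgroup)
        d_bo = dm.get(speciesB, outgroup)
        (ra, fa), (rb, fb) = outgroup_decompose(d_ab, d_ao, d_bo)
        lr.values[(speciesA, est)] = ra
        lr.flags[(speciesA, est)] = fa
        lr.values[(speciesB, est)] = rb
        lr.flags[(speciesB, est)] = fb
        if fa == UNDEFINED:
            lr.notes.append(f"{est}: saturated pairwise input")
    return lr


def locus_rates_ml(
    aln: CodonAlignment,
    topology=None,
    speciesA: str | None = None,
    speciesB: str | None = None,
    kappa: float | str = "estimate",
) -> LocusRates:
    """Terminal ML branch lengths as species rates (estimator ``d``).

    *topology* is a fixed tree over the alignment's record ids; when
    ``None`` the NJ topology from the K2P matrix is used.  A species' rate
    is the mean terminal branch length over its records (paralog rule).
    Only the nucleotide-scale estimator ``d`` is produced on this track;
    the NG86-scale estimators come from the outgroup track.
    """
    if topology is None:
        labels, codes = encode_alignment(aln)
        dm = k2p_matrix_from_codes(labels, codes)
        if dm.any_undefined:
            lr = LocusRates(aln.locus_id, "ml")
            species = (
                [speciesA, speciesB]
                if speciesA and speciesB
                else aln.species
            )
            for sp in species:
                lr.values[(sp, "d")] = float("nan")
                lr.flags[(sp, "d")] = UNDEFINED
            lr.notes.append("saturated K2P matrix; no NJ topology")
            return lr
        topology = nj_tree(dm)
    fitted = ml_branch_lengths(aln, topology, kappa=kappa)
    by_record = {
        lf.taxon.label: lf.edge.length or 0.0 for lf in fitted.leaf_node_iter()
    }
    rec_species = {rid: sp for rid, sp, _ in aln.records}
    lr = LocusRates(aln.locus_id, "ml")
    if not fitted.converged:
        lr.notes.append("ML optimization not converged; best-found lengths")
    wanted = (
        [speciesA, speciesB] if speciesA and speciesB else aln.species
    )
    for sp in wanted:
        lens = [
            by_record[rid] for rid, s in rec_species.items() if s == sp and rid in by_record
        ]
        val, flag = paralog_average(lens)
        if not fitted.converged and flag == OK:
            flag = "nonconverged"
        lr.values[(sp, "d")] = val
        lr.flags[(sp, "d")] = flag
    return lr


def build_rate_table(
    loci: Sequence[CodonAlignment],
    annuals: Sequence[str],
    perennials: Sequence[str],
    outgroup: str,
    estimators: Sequence[str] = ("d", "pN", "pS"),
    method: str = "outgroup",
    kappa: float | str = "estimate",
) -> pd.DataFrame:
    """Paired per-locus rate table for every annual x perennial comparison.

    One row per (locus, annual, perennial, estimator) with the two
    decomposed rates and their flags — the central intermediate artifact of
    the pipeline.  With ``method="ml"`` the estimator ``d`` comes from
    terminal ML branch lengths (pair-independent); NG86-scale estimators
    are always computed on the outgroup track.
    """
    if method not in ("outgroup", "ml"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for aln in loci:
        ml_rates = None
        if method == "ml":
            ml_rates = locus_rates_ml(aln, kappa=kappa)
        og_ests = [e for e in estimators if not (method == "ml" and e == "d")]
        for a in annuals:
            for p in perennials:
                lr = (
                    locus_rates_outgroup(aln, a, p, outgroup, og_ests)
                    if og_ests
                    else None
                )
                for est in estimators:
                    if method == "ml" and est == "d":
                        va, fa = ml_rates.get(a, "d")
                        vp, fp = ml_rates.get(p, "d")
                        src = "ml"
                    else:
                        va, fa = lr.get(a, est)
                        vp, fp = lr.get(p, est)
                        src = "outgroup"
                    rows.append(
                        {
                            "locus_id": aln.locus_id,
                            "annual": a,
                            "perennial": p,
                            "estimator": est,
                            "annual_rate": va,
                            "perennial_rate": vp,
                            "annual_flag": fa,
                            "perennial_flag": fp,
                            "method": src,
                        }
                    )
    return pd.DataFrame(rows)


def rates_to_long_table(rates: Sequence[LocusRates]) -> pd.DataFrame:
    """Long-format rate table: locus_id, method, species, estimator, value, flag."""
    rows = [
        {
            "locus_id": lr.locus_id,
            "method": lr.method,
            "species": sp,
            "estimator": est,
            "value": lr.values[(sp, est)],
            "flag": lr.flags[(sp, est)],
        }
        for lr in rates
        for (sp, est) in lr.values
    ]
    return pd.DataFrame(rows)
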