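"""Multi-locus codon sequence simulation on the five-taxon study topology.

The generator emulates the data regime of the four-dicots-plus-rice
comparison: coding loci evolved on a rooted five-taxon tree (outgroup
``Os``; ``At`` splitting first among the dicots, then ``Mt``, then the
``(Vv, Pt)`` pair), with

* K2P-biased mutation (transition/transversion rate ratio ``kappa``),
* acceptance thinning of nonsynonymous changes with probability ``omega``
  (constant across sites and branches) and hard rejection of stop codons,
* faster *terminal* branches for the annual-like species via per-species
  multipliers,
* i.i.d. gamma-distributed locus rate factors (mean 1) shared by all
  branches of a locus — the knob that produces across-locus rate
  correlation between species,
* optional paralogs: a terminal lineage duplicated at a random time along
  its branch.

Branch lengths are in expected accepted substitutions per nucleotide site;
the continuous-time process is normalized so that the mean accepted rate
over a uniform distribution of sense codons equals one substitution per
site per unit branch length.  Every run is reproducible bit-for-bit from
its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterator

import dendropy
import numpy as np
import pandas as pd

from .alignio import CodonAlignment
from .distances import _code  # shared genetic-code tables

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_locus",
    "simulate_multilocus",
    "preset",
    "PRESETS",
]

#: Rooted study topology; dicot tips are clock-like (equal root-to-tip
#: heights) so that terminal multipliers alone set annual/perennial rate
#: ratios.
DEFAULT_TOPOLOGY = "(Os:0.25,(At:0.15,(Mt:0.11,(Vv:0.07,Pt:0.07):0.04):0.04):0.10);"

#: Variant with a shallower outgroup branch, used by the saturation preset
#: so that outgroup-anchored synonymous distances stay estimable while the
#: annual terminal branches saturate.
SHALLOW_OUTGROUP_TOPOLOGY = (
    "(Os:0.10,(At:0.15,(Mt:0.11,(Vv:0.07,Pt:0.07):0.04):0.04):0.10);"
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the multi-locus codon simulation.

    ``branch_scale`` multiplies every branch of ``topology``; terminal
    multipliers apply on top of it to terminal branches only.  Locus rate
    factors are gamma with shape ``locus_rate_shape`` and mean 1
    (``None`` means no across-locus variation, factor = 1).
    """

    topology: str = DEFAULT_TOPOLOGY
    branch_scale: float = 1.0
    terminal_multipliers: tuple[tuple[str, float], ...] = (("At", 1.5), ("Mt", 1.5))
    kappa: float = 2.0
    omega: float = 0.2
    n_loci: int = 85
    codons_per_locus: int = 300
    locus_rate_shape: float | None = 2.0
    paralog_rate: float = 0.0
    code_id: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1 or self.codons_per_locus < 1:
            raise ValueError("n_loci and codons_per_locus must be >= 1")
        if self.branch_scale < 0 or self.kappa <= 0 or self.omega < 0:
            raise ValueError("rates and scales must be non-negative (kappa > 0)")
        if not (0.0 <= self.paralog_rate <= 1.0):
            raise ValueError("paralog_rate must be a probability")
        if self.locus_rate_shape is not None and self.locus_rate_shape <= 0:
            raise ValueError("locus_rate_shape must be positive or None")

    @property
    def multipliers(self) -> dict[str, float]:
        return dict(self.terminal_multipliers)


@dataclass
class SimulatedDataset:
    """Simulated loci plus per-branch truth bookkeeping."""

    loci: list[CodonAlignment]
    truth: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# codon substitution model


class _CodonModel:
    """Precomputed accepted-rate tables for the thinned K2P codon process."""

    def __init__(self, kappa: float, omega: float, code_id: int):
        aa, stops, sense = _code(code_id)
        self.sense = sense
        self.index = {c: i for i, c in enumerate(sense)}
        nucs = "ACGT"
        ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
        n = len(sense)
        tgt_lists, w_lists, syn_lists = [], [], []
        for codon in sense:
            tgts, ws, syns = [], [], []
            for pos in range(3):
                for nt in nucs:
                    if nt == codon[pos]:
                        continue
                    mutant = codon[:pos] + nt + codon[pos + 1 :]
                    if mutant in stops:
                        continue
                    w = kappa if ts[codon[pos]] == nt else 1.0
                    syn = aa[mutant] == aa[codon]
                    if not syn:
                        w *= omega
                    if w <= 0:
                        continue
                    tgts.append(self.index[mutant])
                    ws.append(w)
                    syns.append(syn)
            tgt_lists.append(np.array(tgts, dtype=np.int16))
            w_lists.append(np.array(ws))
            syn_lists.append(np.array(syns, dtype=bool))
        self.targets = tgt_lists
        self.cum_weights = [np.cumsum(w) for w in w_lists]
        self.is_syn = syn_lists
        self.total_rate = np.array([cw[-1] if len(cw) else 0.0 for cw in self.cum_weights])
        # normalization: mean accepted rate over uniform sense codons == 1
        # substitution per *codon*; branch lengths are per nucleotide site,
        # hence the factor 3 applied at branch level.
        self.mean_rate = float(self.total_rate.mean())


@lru_cache(maxsize=16)
def _model(kappa: float, omega: float, code_id: int) -> _CodonModel:
    return _CodonModel(kappa, omega, code_id)


def _evolve_branch(
    seq: np.ndarray,
    eff_length: float,
    model: _CodonModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, int]:
    """Evolve codon indices along one branch; returns (seq, n_syn, n_nonsyn).

    *eff_length* is in expected substitutions per nucleotide site; the
    per-codon time horizon is ``3 * eff_length / mean_rate``.
    """
    out = seq.copy()
    if eff_length <= 0:
        return out, 0, 0
    T = 3.0 * eff_length / model.mean_rate
    n_syn = n_non = 0
    # first waiting times drawn in bulk; most codons never substitute.
    # codons with zero accepted rate (e.g. Met/Trp at omega=0) never move.
    rates = model.total_rate[out]
    with np.errstate(divide="ignore"):
        first = np.where(
            rates > 0, rng.exponential(1.0, size=out.size) / rates, np.inf
        )
    hot = np.nonzero(first < T)[0]
    for i in hot:
        c = out[i]
        t = first[i]
        while t < T:
            cw = model.cum_weights[c]
            u = rng.random() * cw[-1]
            j = int(np.searchsorted(cw, u, side="right"))
            if model.is_syn[c][j]:
                n_syn += 1
            else:
                n_non += 1
            c = int(model.targets[c][j])
            if model.total_rate[c] <= 0:
                break
            t += rng.exponential(1.0) / model.total_rate[c]
        out[i] = c
    return out, n_syn, n_non


def _codons_to_str(seq: np.ndarray, model: _CodonModel) -> str:
    return "".join(model.sense[i] for i in seq)


@lru_cache(maxsize=32)
def _parse_topology(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def _node_name(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return "+".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def simulate_locus(
    cfg: SimulationConfig,
    locus_factor: float,
    rng: np.random.Generator,
    locus_id: str = "locus",
) -> tuple[CodonAlignment, list[dict]]:
    """Simulate one gap-free codon alignment down the study topology.

    The ancestral sequence is uniform over sense codons; each branch's
    effective length is ``length * branch_scale * locus_factor`` times the
    terminal multiplier for annual-like tips.  With ``paralog_rate`` > 0 a
    terminal lineage may duplicate at a uniform random time along its
    branch, yielding two records for that species.  Returns the alignment
    and per-branch truth rows (realized synonymous/nonsynonymous counts).
    """
    model = _model(cfg.kappa, cfg.omega, cfg.code_id)
    tree = _parse_topology(cfg.topology)
    mult = cfg.multipliers
    root_seq = rng.integers(0, len(model.sense), size=cfg.codons_per_locus)
    records: list[tuple[str, str, str]] = []
    truth: list[dict] = []

    def descend(node: dendropy.Node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            base = (child.edge.length or 0.0) * cfg.branch_scale * locus_factor
            if child.is_leaf():
                sp = child.taxon.label
                eff = base * mult.get(sp, 1.0)
                if cfg.paralog_rate > 0 and rng.random() < cfg.paralog_rate:
                    u = rng.random()
                    stem, s0, n0 = _evolve_branch(seq, eff * u, model, rng)
                    for copy in (1, 2):
                        tipseq, s1, n1 = _evolve_branch(
                            stem, eff * (1.0 - u), model, rng
                        )
                        records.append(
                            (f"{sp}.{copy}", sp, _codons_to_str(tipseq, model))
                        )
                        truth.append(
                            {
                                "locus_id": locus_id,
                                "branch": f"{sp}.{copy}",
                                "species": sp,
                                "eff_length": eff,
                                "n_syn": s0 + s1,
                                "n_nonsyn": n0 + n1,
                            }
                        )
                else:
                    tipseq, s, nn = _evolve_branch(seq, eff, model, rng)
                    records.append((sp, sp, _codons_to_str(tipseq, model)))
                    truth.append(
                        {
                            "locus_id": locus_id,
                            "branch": sp,
                            "species": sp,
                            "eff_length": eff,
                            "n_syn": s,
                            "n_nonsyn": nn,
                        }
                    )
            else:
                childseq, s, nn = _evolve_branch(seq, base, model, rng)
                truth.append(
                    {
                        "locus_id": locus_id,
                        "branch": _node_name(child),
                        "species": "",
                        "eff_length": base,
                        "n_syn": s,
                        "n_nonsyn": nn,
                    }
                )
                descend(child, childseq)

    descend(tree.seed_node, root_seq)
    aln = CodonAlignment(locus_id, records)
    return aln, truth


def simulate_multilocus(cfg: SimulationConfig) -> SimulatedDataset:
    """Simulate ``cfg.n_loci`` independent loci; deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.locus_rate_shape is None:
        factors = np.ones(cfg.n_loci)
    else:
        k = cfg.locus_rate_shape
        factors = rng.gamma(shape=k, scale=1.0 / k, size=cfg.n_loci)
    loci: list[CodonAlignment] = []
    rows: list[dict] = []
    for ell in range(cfg.n_loci):
        locus_id = f"locus{ell:04d}"
        aln, truth = simulate_locus(cfg, float(factors[ell]), rng, locus_id)
        for row in truth:
            row["locus_factor"] = float(factors[ell])
        loci.append(aln)
        rows.extend(truth)
    return SimulatedDataset(loci, pd.DataFrame(rows), cfg)


# ---------------------------------------------------------------------------
# presets: the study regimes


def _nuclear_hk(seed: int) -> SimulationConfig:
    return SimulationConfig(seed=seed)


def _mean_proposal_weights(kappa: float, code_id: int) -> tuple[float, float]:
    """Mean per-codon K2P-weighted synonymous / nonsynonymous proposal rates
    over uniform sense codons (stop targets excluded, no omega thinning)."""
    aa, stops, sense = _code(code_id)
    ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
    sw = nw = 0.0
    for codon in sense:
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                mutant = codon[:pos] + nt + codon[pos + 1 :]
                if mutant in stops:
                    continue
                w = kappa if ts[codon[pos]] == nt else 1.0
                if aa[mutant] == aa[codon]:
                    sw += w
                else:
                    nw += w
    return sw / len(sense), nw / len(sense)


def _chloroplast(seed: int) -> SimulationConfig:
    # plastid loci evolve far slower than nuclear ones: target a synonymous
    # rate 1/4 and a nonsynonymous rate 1/3 of the nuclear preset's.  With
    # the process normalized to one substitution per site per unit length,
    # omega_chl = omega_nuc * (1/3)/(1/4) fixes the dN/dS ratio and the
    # branch scale compensates for the resulting shift in the synonymous
    # share of the total rate.
    omega_nuc = 0.2
    omega_chl = omega_nuc * (1.0 / 3.0) / (1.0 / 4.0)
    sw, nw = _mean_proposal_weights(2.0, 1)
    scale = 0.25 * (sw + omega_chl * nw) / (sw + omega_nuc * nw)
    return SimulationConfig(
        branch_scale=scale,
        omega=omega_chl,
        n_loci=34,
        codons_per_locus=310,
        seed=seed,
    )


def _saturated(seed: int) -> SimulationConfig:
    # deep tree with a doubled At-like terminal: on that branch the
    # decomposed synonymous rate exceeds 1 for most loci (loci saturating
    # beyond the Jukes-Cantor ceiling are a fortiori dS > 1), while the
    # shallow outgroup keeps pairwise synonymous distances estimable.
    return SimulationConfig(
        topology=SHALLOW_OUTGROUP_TOPOLOGY,
        branch_scale=1.8,
        terminal_multipliers=(("At", 2.0), ("Mt", 1.5)),
        locus_rate_shape=6.0,
        seed=seed,
    )


PRESETS = {
    "nuclear_hk": _nuclear_hk,
    "chloroplast": _chloroplast,
    "saturated": _saturated,
}


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """A documented study-regime configuration by name.

    ``nuclear_hk`` — 85 conserved nuclear loci, moderate divergence;
    ``chloroplast`` — 34 slower plastid loci (~1/4 synonymous, ~1/3
    nonsynonymous rate of nuclear); ``saturated`` — deep tree with a
    doubled annual terminal branch producing widespread synonymous
    saturation.  Keyword *overrides* replace individual fields.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name](seed)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
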