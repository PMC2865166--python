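"""Synthetic-data generators with recorded ground truth.

Codon alignments evolve site-by-site along a tree under an MG94-style model
(single-nucleotide moves; non-synonymous moves scaled by the site's omega),
simulated event-by-event so that every realized substitution is recorded.
Co-evolving pairs are engineered by boosting a partner site's
non-synonymous rate for the remainder of any branch on which its driver
site sustains a non-synonymous substitution — the signal a
substitution-mapping co-evolution detector is built to find.

Gene-family sizes evolve by a linear birth--death process with equal birth
and death rate ``lam`` per gene copy per time unit on an ultrametric
species tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import codons
from .seqio import CodonAlignment

__all__ = [
    "SiteClassSpec",
    "CoevolSpec",
    "SimTruth",
    "simulate_codon_alignment",
    "simulate_family_counts",
]


@dataclass
class SiteClassSpec:
    """Mixture of dN/dS site classes plus optional overall rate variation.

    ``classes`` is a list of ``(omega, proportion)``; proportions must sum
    to 1.  If ``gamma_shape`` is set, each site additionally receives an
    overall rate multiplier drawn from Gamma(shape, mean 1); explicit
    ``rate_multipliers`` override the draw.  ``class_overrides`` pins named
    1-based sites to a given class index (useful for engineering sites with
    known behaviour, e.g. the members of a co-evolving pair).
    """

    classes: list[tuple[float, float]]
    gamma_shape: float | None = None
    rate_multipliers: np.ndarray | None = None
    class_overrides: dict[int, int] | None = None

    def __post_init__(self) -> None:
        props = [p for _, p in self.classes]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {sum(props)}, not 1")
        if any(w < 0 for w, _ in self.classes) or any(p < 0 for p in props):
            raise ValueError("omegas and proportions must be non-negative")


@dataclass
class CoevolSpec:
    """Engineered co-evolving codon pairs.

    Each pair is ``(driver, partner)`` in 1-based site coordinates; the
    partner's non-synonymous rate is multiplied by ``coupling`` from the
    moment the driver sustains a non-synonymous substitution on a branch,
    until the end of that branch.
    """

    pairs: list[tuple[int, int]]
    coupling: float = 10.0

    def __post_init__(self) -> None:
        if self.coupling < 1:
            raise ValueError("coupling must be >= 1")
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"pair ({a},{b}) is not two distinct sites")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated alignment."""

    site_classes: np.ndarray          # class index per site
    omegas: np.ndarray                # omega per site
    rate_multipliers: np.ndarray      # overall multiplier per site
    pairs: list[tuple[int, int]]      # engineered (driver, partner) pairs
    branch_ids: list[str]             # edge labels, preorder
    branch_lengths: np.ndarray
    substitutions: list[tuple[str, int, str, str, float, bool]] = field(
        default_factory=list
    )  # (branch_id, site, from_codon, to_codon, time, is_nonsyn)
    nonsyn_counts: np.ndarray | None = None  # branches x sites

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.substitutions,
            columns=["branch", "site", "from_codon", "to_codon", "time", "nonsyn"],
        )


def _edge_list(tree: dendropy.Tree):
    """Preorder (edge_id, parent_node, child_node, length) skipping the root."""
    edges = []
    for k, node in enumerate(tree.preorder_node_iter()):
        if node.parent_node is None:
            continue
        length = node.edge.length if node.edge.length is not None else 0.0
        label = node.taxon.label if node.taxon else f"node{k}"
        edges.append((f"b_{label}", node.parent_node, node, float(length)))
    return edges


class _MG94Machine:
    """Per-state neighbour tables for event-by-event simulation."""

    def __init__(self, exch_rates, codon_freqs):
        rho = np.asarray(exch_rates, float)
        pi = np.asarray(codon_freqs, float)
        pi = pi / pi.sum()
        base = rho[codons.NEI_EXCH] * pi[codons.NEI_TO]
        # normalize so a neutral site (omega = 1, multiplier 1) substitutes
        # at rate 1 at stationarity
        total_by_state = np.bincount(codons.NEI_FROM, weights=base,
                                     minlength=codons.N_CODONS)
        scale = float(np.dot(pi, total_by_state))
        base = base / scale
        order = np.argsort(codons.NEI_FROM, kind="stable")
        self.nei_to = codons.NEI_TO[order]
        self.nei_nonsyn = codons.NEI_NONSYN[order]
        self.base = base[order]
        counts = np.bincount(codons.NEI_FROM, minlength=codons.N_CODONS)
        self.offsets = np.concatenate([[0], np.cumsum(counts)])
        self.pi = pi

    def rates_from(self, state: int, omega: float, mult: float, boost: float):
        lo, hi = self.offsets[state], self.offsets[state + 1]
        r = self.base[lo:hi] * mult
        ns = self.nei_nonsyn[lo:hi]
        r = r * np.where(ns, omega * boost, 1.0)
        return self.nei_to[lo:hi], ns, r


def _evolve_site_on_branch(machine, rng, state, t_total, omega, mult,
                           coupling, boost_time):
    """Gillespie simulation of one site along one branch.

    Returns (end_state, events, first_nonsyn_time).  ``boost_time`` is the
    time (from branch start) at which the non-synonymous boost switches on,
    or None.  Rates are piecewise constant, so on crossing the boundary the
    waiting time is redrawn (memorylessness makes this exact).
    """
    t = 0.0
    events = []
    first_ns = None
    boosted = boost_time is not None and boost_time <= 0.0
    while True:
        boost = coupling if boosted else 1.0
        to, ns, rates = machine.rates_from(state, omega, mult, boost)
        total = rates.sum()
        if total <= 0:
            if not boosted and boost_time is not None:
                boosted = True
                t = boost_time
                continue
            break
        w = rng.exponential(1.0 / total)
        if not boosted and boost_time is not None and t + w > boost_time:
            t = boost_time
            boosted = True
            continue
        t = t + w
        if t >= t_total:
            break
        k = rng.choice(len(rates), p=rates / total)
        new_state = int(to[k])
        is_ns = bool(ns[k])
        events.append((state, new_state, t, is_ns))
        if is_ns and first_ns is None:
            first_ns = t
        state = new_state
    return state, events, first_ns


def _evolve_pair_on_branch(machine, rng, sa, sb, t_total, oa, ob, ma, mb,
                           coupling):
    """Joint Gillespie simulation of a mutually coupled site pair.

    Each site's non-synonymous rate is multiplied by ``coupling`` from the
    moment the *other* site sustains a non-synonymous substitution on the
    branch.  Returns (end_a, end_b, events_a, events_b).
    """
    t = 0.0
    boost_a = boost_b = False
    ev_a: list = []
    ev_b: list = []
    while True:
        to_a, ns_a, ra = machine.rates_from(sa, oa, ma,
                                            coupling if boost_a else 1.0)
        to_b, ns_b, rb = machine.rates_from(sb, ob, mb,
                                            coupling if boost_b else 1.0)
        total = ra.sum() + rb.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= t_total:
            break
        if rng.random() < ra.sum() / total:
            k = rng.choice(len(ra), p=ra / ra.sum())
            new = int(to_a[k]); is_ns = bool(ns_a[k])
            ev_a.append((sa, new, t, is_ns))
            sa = new
            if is_ns:
                boost_b = True
        else:
            k = rng.choice(len(rb), p=rb / rb.sum())
            new = int(to_b[k]); is_ns = bool(ns_b[k])
            ev_b.append((sb, new, t, is_ns))
            sb = new
            if is_ns:
                boost_a = True
    return sa, sb, ev_a, ev_b


def simulate_codon_alignment(
    tree: dendropy.Tree,
    n_codons: int,
    classes: SiteClassSpec,
    coevol: CoevolSpec | None = None,
    nucleotide_params=None,
    codon_frequencies=None,
    seed: int = 0,
) -> tuple[CodonAlignment, SimTruth]:
    """Simulate a codon alignment on ``tree`` with known site structure."""
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree needs at least 2 leaves")
    if n_codons < 1:
        raise ValueError("n_codons must be positive")
    rng = np.random.default_rng(seed)
    rho = (np.ones(6) if nucleotide_params is None
           else np.asarray(nucleotide_params, float))
    pi = (np.full(codons.N_CODONS, 1.0 / codons.N_CODONS)
          if codon_frequencies is None else np.asarray(codon_frequencies, float))
    machine = _MG94Machine(rho, pi)

    # site classes and rate multipliers
    props = np.array([p for _, p in classes.classes])
    omg = np.array([w for w, _ in classes.classes])
    site_cls = rng.choice(len(omg), size=n_codons, p=props / props.sum())
    if classes.class_overrides:
        for site, cls in classes.class_overrides.items():
            if not 1 <= site <= n_codons:
                raise ValueError(f"override site {site} outside 1..{n_codons}")
            if not 0 <= cls < len(omg):
                raise ValueError(f"override class {cls} out of range")
            site_cls[site - 1] = cls
    omegas = omg[site_cls]
    if classes.rate_multipliers is not None:
        mults = np.asarray(classes.rate_multipliers, float)
        if mults.shape != (n_codons,):
            raise ValueError("rate_multipliers length mismatch")
    elif classes.gamma_shape is not None:
        a = classes.gamma_shape
        mults = rng.gamma(a, 1.0 / a, size=n_codons)
    else:
        mults = np.ones(n_codons)

    pairs = list(coevol.pairs) if coevol else []
    coupling = coevol.coupling if coevol else 1.0
    for a, b in pairs:
        if not (1 <= a <= n_codons and 1 <= b <= n_codons):
            raise ValueError(f"pair ({a},{b}) outside 1..{n_codons}")
    # a pair listed in both orientations is mutually coupled and simulated
    # jointly; otherwise coupling is one-way (driver before partner)
    pair_set = set(pairs)
    mutual: list[tuple[int, int]] = sorted(
        {(min(a, b), max(a, b)) for a, b in pairs if (b, a) in pair_set}
    )
    mutual_sites = {s for p in mutual for s in p}
    partner_of = {}  # partner site -> driver site (first pairing wins)
    for drv, prt in pairs:
        if prt not in mutual_sites:
            partner_of.setdefault(prt, drv)
    drivers = {d for d, p in pairs if p in partner_of and partner_of[p] == d}
    site_order = (
        sorted(drivers)
        + [s for s in range(1, n_codons + 1)
           if s not in drivers and s not in mutual_sites]
    )

    root_states = rng.choice(codons.N_CODONS, size=n_codons, p=machine.pi)
    edges = _edge_list(tree)
    branch_ids = [e[0] for e in edges]
    branch_lengths = np.array([e[3] for e in edges])
    nonsyn = np.zeros((len(edges), n_codons), dtype=np.int64)
    subs: list[tuple[str, int, str, str, float, bool]] = []

    node_states: dict[int, np.ndarray] = {id(tree.seed_node): root_states}
    for bidx, (bid, parent, child, length) in enumerate(edges):
        start = node_states[id(parent)].copy()
        end = start.copy()
        first_ns_at: dict[int, float] = {}
        for sa_site, sb_site in mutual:
            ea, eb, ev_a, ev_b = _evolve_pair_on_branch(
                machine, rng, int(start[sa_site - 1]), int(start[sb_site - 1]),
                length, float(omegas[sa_site - 1]), float(omegas[sb_site - 1]),
                float(mults[sa_site - 1]), float(mults[sb_site - 1]), coupling,
            )
            end[sa_site - 1], end[sb_site - 1] = ea, eb
            for site, events in ((sa_site, ev_a), (sb_site, ev_b)):
                for s0, s1, t, is_ns in events:
                    subs.append((bid, site, codons.SENSE_CODONS[s0],
                                 codons.SENSE_CODONS[s1], t, is_ns))
                    if is_ns:
                        nonsyn[bidx, site - 1] += 1
        for site in site_order:
            drv = partner_of.get(site)
            boost_time = first_ns_at.get(drv) if drv is not None else None
            cpl = coupling if drv is not None else 1.0
            st, events, first_ns = _evolve_site_on_branch(
                machine, rng, int(start[site - 1]), length,
                float(omegas[site - 1]), float(mults[site - 1]),
                cpl, boost_time,
            )
            end[site - 1] = st
            if first_ns is not None and site in drivers:
                first_ns_at[site] = first_ns
            for s0, s1, t, is_ns in events:
                subs.append((bid, site, codons.SENSE_CODONS[s0],
                             codons.SENSE_CODONS[s1], t, is_ns))
                if is_ns:
                    nonsyn[bidx, site - 1] += 1
        node_states[id(child)] = end

    taxa, rows = [], []
    for lf in leaves:
        taxa.append(lf.taxon.label)
        states = node_states[id(lf)]
        rows.append("".join(codons.SENSE_CODONS[s] for s in states))
    aln = CodonAlignment(taxa, rows)
    truth = SimTruth(site_cls, omegas, mults, pairs, branch_ids,
                     branch_lengths, subs, nonsyn)
    return aln, truth


def simulate_family_counts(
    species_tree: dendropy.Tree,
    lam: float,
    root_size: int,
    n_families: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[dict[str, int]]]:
    """Evolve gene-family sizes by a linear birth--death process.

    Returns a count table (rows = families, columns = species) and, per
    family, the full history of sizes at every node (keyed by taxon label
    for leaves and ``nodeK`` for internals).
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if root_size < 1:
        raise ValueError("root_size must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = list(species_tree.preorder_node_iter())
    labels = {}
    for k, nd in enumerate(nodes):
        labels[id(nd)] = nd.taxon.label if nd.taxon else f"node{k}"
    leaf_labels = [lf.taxon.label for lf in species_tree.leaf_node_iter()]

    histories: list[dict[str, int]] = []
    table = np.zeros((n_families, len(leaf_labels)), dtype=np.int64)
    for fam in range(n_families):
        sizes = {id(species_tree.seed_node): root_size}
        hist = {labels[id(species_tree.seed_node)]: root_size}
        for nd in nodes:
            if nd.parent_node is None:
                continue
            t = nd.edge.length if nd.edge.length is not None else 0.0
            n = sizes[id(nd.parent_node)]
            elapsed = 0.0
            while n > 0:
                rate = 2.0 * lam * n
                if rate <= 0:
                    break
                elapsed += rng.exponential(1.0 / rate)
                if elapsed >= t:
                    break
                n += 1 if rng.random() < 0.5 else -1
            sizes[id(nd)] = n
            hist[labels[id(nd)]] = n
        histories.append(hist)
        for j, lab in enumerate(leaf_labels):
            table[fam, j] = hist[lab]
    df = pd.DataFrame(table, columns=leaf_labels,
                      index=[f"fam{f}" for f in range(n_families)])
    return df, histories
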