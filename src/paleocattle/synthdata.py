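"""Synthetic data generators with the statistical structure the analysis assumes.

Three generators, all pure functions of (config, seed):

* a serial-sampling (heterochronous) coalescent with infinite-sites mutation,
  emulating cohorts of aligned mtDNA fragments whose samples have different
  ages — the process behind the diversity statistics and the heterochrony
  correction;
* a haplogroup panel generator that plants diagnostic alleles from a rule
  set, sprinkles private mutations at non-diagnostic sites and assigns
  periods, regions, sexes and Y alleles, recording truth labels;
* a multinomial cohort-count generator for calibrating the frequency tests.

Time scaling: pairwise coalescence at rate 1/(2*Ne) per generation, so with
theta = 4*Ne*mu*L the expected mean pairwise difference K of an isochronous
sample equals theta.  Sample ages in years are converted to generations via
the generation length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .haplogroups import HaplogroupRuleSet
from .haplotyping import ContingencyTable
from .seqio import (
    AlignedSeqSet,
    CircularReference,
    Regions,
    RegionSpec,
    SampleRecord,
    region_positions,
)

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SerialCoalescentConfig:
    """Configuration of the heterochronous coalescent generator.

    n samples with ages in years BP; Ne is the (diploid-equivalent) effective
    size entering the 1/(2*Ne) pairwise coalescence rate; mu is the per-site
    per-generation mutation rate over L sites.
    """

    n: int
    ages: tuple[float, ...]
    Ne: float
    generation_length: float
    mu: float
    L: int
    seed: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2")
        if len(self.ages) != self.n:
            raise ValueError("ages must have one entry per sample")
        if min(self.Ne, self.generation_length, self.L) <= 0 or self.mu < 0:
            raise ValueError("rates and sizes must be positive")

    @property
    def theta(self) -> float:
        """Population-scaled diversity 4*Ne*mu*L (expected K, per sequence)."""
        return 4.0 * self.Ne * self.mu * self.L


def _simulate_genealogy(cfg: SerialCoalescentConfig, rng: np.random.Generator):
    """Serial Kingman coalescent; returns (parent, branch_length) per node.

    Node ids 0..n-1 are tips; internal nodes are appended.  Branch lengths in
    generations.  Lineages activate (looking backwards) at their sampling
    times; while k lineages are active, the next coalescence is exponential
    with rate C(k,2)/(2*Ne).
    """
    ages_gen = np.asarray(cfg.ages, dtype=float) / cfg.generation_length
    order = np.argsort(ages_gen)
    parent: dict[int, int] = {}
    blen: dict[int, float] = {}
    node_time: dict[int, float] = {i: float(ages_gen[i]) for i in range(cfg.n)}

    active: list[int] = []
    pending = list(order)  # tips not yet activated, by increasing age
    t = float(ages_gen[order[0]])
    next_node = cfg.n
    while pending or len(active) > 1:
        while pending and ages_gen[pending[0]] <= t + 1e-12:
            active.append(int(pending.pop(0)))
        k = len(active)
        next_activation = float(ages_gen[pending[0]]) if pending else np.inf
        if k < 2:
            t = next_activation
            continue
        rate = k * (k - 1) / 2.0 / (2.0 * cfg.Ne)
        wait = rng.exponential(1.0 / rate)
        if t + wait >= next_activation:
            t = next_activation
            continue
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        anc = next_node
        next_node += 1
        node_time[anc] = t
        for child in (a, b):
            parent[child] = anc
            blen[child] = t - node_time[child]
        active = [x for x in active if x not in (a, b)] + [anc]
    root = active[0]
    return parent, blen, node_time, root


def simulate_serial_coalescent(
    cfg: SerialCoalescentConfig,
) -> tuple[AlignedSeqSet, list[SampleRecord], dict]:
    """Simulate a heterochronous alignment with known truth.

    Mutations are Poisson on branches (rate mu per site per generation) and
    mapped to distinct uniformly chosen positions (infinite sites; collisions
    re-drawn), each changing the reference base to a different random base.
    Returns (alignment, metadata records, truth dict).
    """
    rng = np.random.default_rng(cfg.seed)
    parent, blen, node_time, root = _simulate_genealogy(cfg, rng)

    ref = rng.choice(BASES, size=cfg.L)
    total_branch = float(sum(blen.values()))
    n_mut = rng.poisson(cfg.mu * cfg.L * total_branch) if cfg.mu > 0 else 0

    # place mutations on branches proportionally to length, at distinct sites
    nodes = list(blen)
    lengths = np.array([blen[v] for v in nodes], dtype=float)
    used: set[int] = set()
    mutations: dict[int, list[tuple[int, str]]] = {v: [] for v in nodes}
    if n_mut > cfg.L:
        raise ValueError("more mutations than sites; increase L or lower mu")
    for _ in range(n_mut):
        v = nodes[int(rng.choice(len(nodes), p=lengths / lengths.sum()))]
        while True:
            pos = int(rng.integers(cfg.L))
            if pos not in used:
                used.add(pos)
                break
        old = ref[pos]
        new = str(rng.choice(BASES[BASES != old]))
        mutations[v].append((pos, new))

    # propagate sequences root -> tips
    children: dict[int, list[int]] = {}
    for child, par in parent.items():
        children.setdefault(par, []).append(child)
    seqs: dict[int, np.ndarray] = {root: ref.copy()}
    stack = [root]
    while stack:
        v = stack.pop()
        for c in children.get(v, []):
            s = seqs[v].copy()
            for pos, new in mutations[c]:
                s[pos] = new
            seqs[c] = s
            stack.append(c)

    region = RegionSpec(1, cfg.L, CircularReference("sim", cfg.L))
    ids = [f"S{i + 1:03d}" for i in range(cfg.n)]
    aln = AlignedSeqSet(ids, region.positions(), ["".join(seqs[i]) for i in range(cfg.n)])
    records = [
        SampleRecord(id=ids[i], site="sim", region="sim", age_bp=float(cfg.ages[i]))
        for i in range(cfg.n)
    ]
    truth = {
        "theta": cfg.theta,
        "n_mutations": int(n_mut),
        "total_branch_generations": total_branch,
        "tree_height_generations": float(max(node_time.values()) - min(node_time.values())),
        "seed": cfg.seed,
    }
    return aln, records, truth


# --- haplogroup / cohort panel ---------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """One cohort of a synthetic panel."""

    period: str
    region: str
    size: int
    haplogroup_freqs: Mapping[str, float]
    y1_freq: float = 0.5
    male_frac: float = 0.5


@dataclass(frozen=True)
class PanelPlan:
    """Plan of a synthetic ancient/modern panel.

    ``private_rate`` is the per-site probability of a private substitution at
    non-diagnostic positions (diagnostic sites are never touched, so the
    planted labels remain exactly recoverable).
    """

    cohorts: tuple[CohortSpec, ...]
    private_rate: float = 0.0

    def __post_init__(self) -> None:
        for c in self.cohorts:
            if c.size <= 0:
                raise ValueError(f"cohort {c.period}/{c.region}: size must be positive")
            tot = sum(c.haplogroup_freqs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(
                    f"cohort {c.period}/{c.region}: haplogroup frequencies sum to {tot}"
                )


PERIOD_DATES = {
    "Prehistoric": (-700.0, 1200.0),
    "Medieval": (1200.0, 1550.0),
    "Post-Medieval": (1550.0, 1800.0),
    "Modern": (1800.0, 2000.0),
}


def _reference_alleles(rules: HaplogroupRuleSet, rng: np.random.Generator) -> dict[int, str]:
    """Background allele per diagnostic position: the default-path allele when
    required, else a base contradicting no-default rules cannot avoid — pick a
    base not required by any non-default rule at that position."""
    background: dict[int, str] = {}
    default_profile = rules.path_profile(rules.default_label)
    for pos in rules.diagnostic_positions:
        if pos in default_profile:
            background[pos] = default_profile[pos]
            continue
        claimed = {
            r.required[pos]
            for r in rules.rules
            if pos in r.required
        }
        free = [b for b in "ACGT" if b not in claimed]
        background[pos] = free[0] if free else str(rng.choice(BASES))
    return background


def simulate_panel(
    plan: PanelPlan,
    rules: HaplogroupRuleSet,
    region: Regions,
    seed: int,
) -> tuple[AlignedSeqSet, list[SampleRecord], dict]:
    """Synthetic panel with planted haplogroup profiles and Y alleles.

    ``region`` may be one fragment or the marker design's list of disjoint
    fragments; it must cover every diagnostic position of ``rules``.  Returns
    (mt alignment, metadata, truth) where truth records the planted
    haplogroup label and Y haplotype per sample.  Y alleles use the default
    G=Y2 / T=Y1 mapping at a virtual site carried in the truth record.
    """
    rng = np.random.default_rng(seed)
    positions = region_positions(region)
    pos_index = {p: i for i, p in enumerate(positions)}
    missing = [p for p in rules.diagnostic_positions if p not in pos_index]
    if missing:
        raise ValueError(f"region does not cover diagnostic positions {sorted(missing)}")

    background = rng.choice(BASES, size=len(positions))
    for pos, allele in _reference_alleles(rules, rng).items():
        background[pos_index[pos]] = allele

    ids: list[str] = []
    rows: list[str] = []
    records: list[SampleRecord] = []
    truth_labels: dict[str, str] = {}
    truth_y: dict[str, str] = {}
    diag_idx = {pos_index[p] for p in rules.diagnostic_positions}

    counter = 0
    for cohort in plan.cohorts:
        groups = sorted(cohort.haplogroup_freqs)
        probs = np.array([cohort.haplogroup_freqs[g] for g in groups])
        assignment = rng.choice(len(groups), size=cohort.size, p=probs)
        lo, hi = PERIOD_DATES.get(cohort.period, (1800.0, 2000.0))
        for g_i in assignment:
            counter += 1
            sid = f"P{counter:03d}"
            label = groups[int(g_i)]
            seq = background.copy()
            for pos, allele in rules.path_profile(label).items():
                seq[pos_index[pos]] = allele
            if plan.private_rate > 0:
                for i in range(len(seq)):
                    if i not in diag_idx and rng.random() < plan.private_rate:
                        seq[i] = str(rng.choice(BASES[BASES != seq[i]]))
            male = rng.random() < cohort.male_frac
            date = float(rng.uniform(lo, hi))
            ids.append(sid)
            rows.append("".join(seq))
            records.append(
                SampleRecord(
                    id=sid,
                    site="synthetic",
                    region=cohort.region,
                    period=cohort.period,
                    date_early=date,
                    date_late=date,
                    sex="male" if male else "female",
                )
            )
            truth_labels[sid] = label
            if male:
                truth_y[sid] = "Y1" if rng.random() < cohort.y1_freq else "Y2"

    aln = AlignedSeqSet(ids, positions, rows)

    # 155 bp UTY19 fragments for the male samples (G=Y2 / T=Y1 at site 423)
    y_region = RegionSpec(350, 504, CircularReference("Y_sim", 1000))
    y_pos = y_region.positions()
    site_idx = y_pos.index(423)
    y_ids, y_rows = [], []
    for sid, yhap in truth_y.items():
        frag = rng.choice(BASES, size=len(y_pos))
        frag[site_idx] = "T" if yhap == "Y1" else "G"
        y_ids.append(sid)
        y_rows.append("".join(frag))
    y_aln = AlignedSeqSet(y_ids, y_pos, y_rows)

    truth = {
        "haplogroup": truth_labels,
        "y_haplotype": truth_y,
        "y_alignment": y_aln,
        "seed": seed,
    }
    return aln, records, truth


def simulate_cohort_counts(
    probabilities: Sequence[Sequence[float]],
    sizes: Sequence[int],
    replicates: int,
    seed: int,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> list[ContingencyTable]:
    """Independent multinomial count tables, one row per cohort.

    ``probabilities[i]`` is the category distribution of cohort i (each must
    sum to 1); ``sizes[i]`` its sample size.  Returns ``replicates`` tables.
    """
    probs = [np.asarray(p, dtype=float) for p in probabilities]
    for p in probs:
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("each probability vector must be non-negative and sum to 1")
    if len(probs) != len(sizes):
        raise ValueError("need one size per cohort")
    k = len(probs[0])
    rng = np.random.default_rng(seed)
    rl = list(row_labels) if row_labels else [f"cohort{i + 1}" for i in range(len(probs))]
    cl = list(col_labels) if col_labels else [f"cat{j + 1}" for j in range(k)]
    out = []
    for _ in range(replicates):
        counts = np.vstack([rng.multinomial(n, p) for n, p in zip(sizes, probs)])
        out.append(ContingencyTable(list(rl), list(cl), counts))
    return out
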