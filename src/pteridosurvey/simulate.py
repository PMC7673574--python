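"""Synthetic-flora generator.

Emulates the statistical structure of a molecular pteridophyte survey so
every pipeline stage runs at desk scale with no downloads: a Yule species
tree, Jukes–Cantor sequence evolution of a ~1.3 kb plastid barcode, a small
set of taxon pairs forced to share a haplotype (the maternally inherited
plastid of putative hybrids), multiple specimens for some taxa, a fraction
of partial (half-length) sequences, and per-day Bernoulli detection over a
season of sampling days.

Defaults mirror the survey the pipeline targets: 176 species, 1,309 bp,
37 collection days, and enough shared-haplotype pairs to give a failure
rate near one taxon in five.  All randomness flows from one seeded
generator stream in a fixed order, so one seed gives byte-identical output
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .distances import build_distance_matrix
from .io import (
    AlignedSequenceSet,
    IncidenceMatrix,
    SurveyChecklist,
    TaxonRecord,
)

__all__ = [
    "SimulationConfig",
    "simulate_flora",
    "simulate_three_floras",
]

#: Families treated as lycophytes by the checklist summary.
_LYCO_FAMILIES = ("Lycopodiaceae", "Selaginellaceae")
_FERN_FAMILIES = (
    "Dryopteridaceae",
    "Polypodiaceae",
    "Hymenophyllaceae",
    "Aspleniaceae",
    "Pteridaceae",
    "Thelypteridaceae",
    "Cyatheaceae",
    "Athyriaceae",
)

#: Growth-habit inclusion probabilities: the observed per-habit proportions
#: of terminal taxa in the target survey (multi-label, so they exceed 1).
DEFAULT_HABIT_PROBS = {
    "climbing": 5 / 178,
    "epipetric": 19 / 178,
    "epiphytic": 94 / 178,
    "terrestrial": 74 / 178,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic flora.

    ``subst_rate`` is the expected number of substitutions per site from
    the root to any tip (the Yule tree is ultrametric and rescaled to this
    depth).  ``n_failure_pairs`` taxon pairs share one haplotype exactly;
    these are the designated barcode failures recorded in the truth set.
    ``detection_beta`` gives the Beta(a, b) law of each species' daily
    detection probability.
    """

    n_species: int = 176
    seq_length: int = 1309
    birth_rate: float = 1.0
    subst_rate: float = 0.08
    n_failure_pairs: int = 15
    p_single_specimen: float = 0.8
    max_specimens: int = 5
    T: int = 37
    detection_beta: tuple[float, float] = (2.0, 2.0)
    habit_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HABIT_PROBS)
    )
    partial_fraction: float = 0.015
    lycophyte_fraction: float = 0.04
    n_nonnative: int = 1
    flora: str = "synthetic"
    seed: int | None = None
    max_redraws: int = 20

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.birth_rate <= 0 or self.subst_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.n_failure_pairs * 2 > self.n_species:
            raise ValueError("n_failure_pairs must be <= n_species / 2")
        for p in (self.p_single_specimen, self.partial_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        for p in self.habit_probs.values():
            if not 0 <= p <= 1:
                raise ValueError("habit probabilities must be in [0, 1]")
        if self.T < 1:
            raise ValueError("T must be >= 1")


class _SimNode:
    __slots__ = ("children", "length", "tip_index")

    def __init__(self) -> None:
        self.children: list[_SimNode] = []
        self.length: float = 0.0
        self.tip_index: int | None = None


def _yule_tree(
    rng: np.random.Generator, n_tips: int, birth_rate: float, depth: float
) -> tuple[_SimNode, np.ndarray]:
    """Ultrametric Yule tree with n_tips, rescaled to the given depth.

    Returns the root and the per-tip pendant branch lengths (post-scaling),
    indexed by tip_index (assignment order is the order lineages appear).
    """
    root = _SimNode()
    start = {id(root): 0.0}
    active = [root]
    # root immediately bifurcates: begin with 2 lineages
    now = 0.0
    for child in (_SimNode(), _SimNode()):
        root.children.append(child)
        start[id(child)] = now
        active = root.children[:]
    while len(active) < n_tips:
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.length = now - start[id(node)]
        for _ in range(2):
            child = _SimNode()
            start[id(child)] = now
            node.children.append(child)
            active.append(child)
    now += rng.exponential(1.0 / (birth_rate * len(active)))
    pendant = np.empty(n_tips)
    for i, node in enumerate(active):
        node.length = now - start[id(node)]
        node.tip_index = i
        pendant[i] = node.length
    scale = depth / now
    stack = [root]
    while stack:
        node = stack.pop()
        node.length *= scale
        stack.extend(node.children)
    return root, pendant * scale


def _evolve_jc(
    rng: np.random.Generator, root: _SimNode, n_sites: int, n_tips: int
) -> np.ndarray:
    """Site-independent Jukes–Cantor evolution; returns tip x site codes."""
    tips = np.empty((n_tips, n_sites), dtype=np.uint8)
    root_seq = rng.integers(0, 4, size=n_sites, dtype=np.uint8)
    stack: list[tuple[_SimNode, np.ndarray]] = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.tip_index is not None:
            tips[node.tip_index] = seq
            continue
        for child in node.children:
            p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * child.length))
            mask = rng.random(n_sites) < p
            new = seq.copy()
            k = int(mask.sum())
            if k:
                shift = rng.integers(1, 4, size=k, dtype=np.uint8)
                new[mask] = (new[mask] + shift) % 4
            stack.append((child, new))
    return tips


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray, partial: str | None = None) -> str:
    """Codes -> string; 'partial' masks the 5' or 3' half with N."""
    out = _BASES[codes].copy()
    half = codes.size // 2
    if partial == "5prime":  # only the 5' half was read
        out[half:] = ord("N")
    elif partial == "3prime":
        out[:half] = ord("N")
    return out.tobytes().decode("ascii")


def _adjusted_habit_probs(habit_probs: dict[str, float]) -> dict[str, float]:
    """Deflate per-habit Bernoulli probabilities so that, conditional on a
    taxon having at least one habit, each habit's marginal equals the
    configured proportion.  Fixed point of p'_h = p_h (1 - prod(1 - p'))."""
    items = sorted(habit_probs.items())
    adj = {h: p for h, p in items}
    for _ in range(200):
        z = 1.0
        for h, _ in items:
            z *= 1.0 - adj[h]
        new = {h: min(p * (1.0 - z), 1.0) for h, p in items}
        if max(abs(new[h] - adj[h]) for h, _ in items) < 1e-12:
            adj = new
            break
        adj = new
    return adj


def _draw_habits(
    rng: np.random.Generator, habit_probs: dict[str, float]
) -> frozenset[str]:
    adj = _adjusted_habit_probs(habit_probs)
    while True:
        habits = [h for h in sorted(adj) if rng.random() < adj[h]]
        if habits:
            return frozenset(habits)


def _zero_distance_taxon_pairs(
    aln: AlignedSequenceSet, specimen_map: dict[str, str]
) -> set[frozenset[str]]:
    """Taxon pairs connected by at least one zero-distance specimen pair."""
    dm = build_distance_matrix(aln, min_overlap=1)
    pairs: set[frozenset[str]] = set()
    zero = (dm.d == 0.0) & dm.defined
    idx = np.argwhere(np.triu(zero, k=1))
    for i, j in idx:
        ta = specimen_map[dm.specimen_ids[i]]
        tb = specimen_map[dm.specimen_ids[j]]
        if ta != tb:
            pairs.add(frozenset((ta, tb)))
    return pairs


def simulate_flora(
    cfg: SimulationConfig,
) -> tuple[AlignedSequenceSet, SurveyChecklist, IncidenceMatrix, dict]:
    """Simulate one flora: alignment, checklist, incidence and truth record.

    The truth record lists the exact designated failure pairs, the true
    (including undetected) species richness, and the per-species daily
    detection probabilities.  Haplotype collisions that would make a
    non-designated taxon pair identical trigger a re-draw; exceeding the
    re-draw limit raises ``RuntimeError`` (unsatisfiable configuration).
    """
    rng = np.random.default_rng(cfg.seed)
    for _attempt in range(cfg.max_redraws):
        result = _simulate_once(cfg, rng)
        if result is not None:
            return result
    raise RuntimeError(
        "simulate_flora: haplotype-collision re-draw limit exceeded; "
        "increase subst_rate or seq_length, or reduce n_species"
    )


def _simulate_once(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_species
    root, _ = _yule_tree(rng, n, cfg.birth_rate, cfg.subst_rate)
    haplo = _evolve_jc(rng, root, cfg.seq_length, n)

    names = [f"Taxon sp{i + 1:03d}" for i in range(n)]
    fail_idx = rng.choice(n, size=2 * cfg.n_failure_pairs, replace=False)
    failure_pairs: list[tuple[str, str]] = []
    for k in range(cfg.n_failure_pairs):
        a, b = int(fail_idx[2 * k]), int(fail_idx[2 * k + 1])
        haplo[b] = haplo[a]
        failure_pairs.append((names[a], names[b]))
    failure_taxa = {t for pair in failure_pairs for t in pair}

    # specimens: first carries the exact haplotype; extras may carry one
    # private mutation; a small fraction are half-length partial reads
    specimen_ids: list[str] = []
    specimen_rows: list[str] = []
    specimen_map: dict[str, str] = {}
    counts = np.empty(n, dtype=int)
    for i in range(n):
        if rng.random() < cfg.p_single_specimen:
            counts[i] = 1
        else:
            counts[i] = rng.integers(2, cfg.max_specimens + 1)
        for j in range(counts[i]):
            seq = haplo[i].copy()
            if j > 0 and rng.random() < 0.5:
                site = rng.integers(cfg.seq_length)
                seq[site] = (seq[site] + rng.integers(1, 4)) % 4
            partial = None
            if rng.random() < cfg.partial_fraction:
                partial = "5prime" if rng.random() < 0.5 else "3prime"
            sid = f"{cfg.flora}-{i + 1:03d}-{j + 1}"
            specimen_ids.append(sid)
            specimen_rows.append(_decode(seq, partial))
            specimen_map[sid] = names[i]

    # incidence: Bernoulli(p_i) per day; designated failure taxa are
    # conditioned on >=1 detection so the truth set survives into the data
    a_beta, b_beta = cfg.detection_beta
    detect_p = rng.beta(a_beta, b_beta, size=n)
    rows = (rng.random((n, cfg.T)) < detect_p[:, None]).astype(np.int8)
    for i in range(n):
        if names[i] in failure_taxa and rows[i].sum() == 0:
            for _ in range(1000):
                rows[i] = (rng.random(cfg.T) < detect_p[i]).astype(np.int8)
                if rows[i].sum():
                    break
            else:
                rows[i, rng.integers(cfg.T)] = 1
    detected = rows.sum(axis=1) > 0

    detected_names = {names[i] for i in range(n) if detected[i]}
    kept = [
        (sid, row)
        for sid, row in zip(specimen_ids, specimen_rows)
        if specimen_map[sid] in detected_names
    ]
    kept_ids = [sid for sid, _ in kept]
    aln = AlignedSequenceSet(
        tuple(kept_ids), tuple(row for _, row in kept)
    )

    designated = {frozenset(p) for p in failure_pairs}
    if _zero_distance_taxon_pairs(aln, specimen_map) != designated:
        return None  # collision with a non-designated pair: redraw

    # checklist metadata
    n_lyco = int(round(cfg.lycophyte_fraction * n))
    nonnative = set(
        rng.choice(n, size=min(cfg.n_nonnative, n), replace=False).tolist()
    )
    records: dict[str, TaxonRecord] = {}
    for i in range(n):
        if not detected[i]:
            continue
        if i < n_lyco:
            family = _LYCO_FAMILIES[i % len(_LYCO_FAMILIES)]
        else:
            family = _FERN_FAMILIES[(i // 3) % len(_FERN_FAMILIES)]
        records[names[i]] = TaxonRecord(
            name=names[i],
            rank="species",
            genus=f"{family[:4]}genus{(i // 3) + 1:02d}",
            family=family,
            growth_habits=_draw_habits(rng, cfg.habit_probs),
            native=i not in nonnative,
            floras=frozenset({cfg.flora}),
        )
    checklist = SurveyChecklist(
        records,
        {s: t for s, t in specimen_map.items() if t in detected_names},
        {s: cfg.flora for s in kept_ids},
    )

    inc = IncidenceMatrix(
        tuple(names[i] for i in range(n) if detected[i]),
        tuple(f"day{d + 1:02d}" for d in range(cfg.T)),
        rows[detected],
    )
    truth = {
        "true_richness": n,
        "observed_richness": int(detected.sum()),
        "undetected": sorted(
            names[i] for i in range(n) if not detected[i]
        ),
        "failure_pairs": [sorted(p) for p in failure_pairs],
        "failure_taxa": sorted(failure_taxa),
        "detection_probabilities": {
            names[i]: float(detect_p[i]) for i in range(n)
        },
        "specimens_per_taxon": {names[i]: int(counts[i]) for i in range(n)},
    }
    return aln, checklist, inc, truth


def _nearest_neighbor_distances(
    root: _SimNode, n_tips: int
) -> np.ndarray:
    """Patristic distance from each tip to its closest other tip."""
    # tip-to-tip distances by post-order merging of tip depth lists
    nn = np.full(n_tips, np.inf)

    def walk(node: _SimNode) -> list[tuple[int, float]]:
        if node.tip_index is not None:
            return [(node.tip_index, node.length)]
        groups = [walk(child) for child in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for ti, di in groups[gi]:
                    for tj, dj in groups[gj]:
                        d = di + dj
                        if d < nn[ti]:
                            nn[ti] = d
                        if d < nn[tj]:
                            nn[tj] = d
        merged = [(t, d + node.length) for g in groups for t, d in g]
        return merged

    walk(root)
    return nn


def simulate_three_floras(
    cfgs: Sequence[SimulationConfig],
    shared_fraction: float = 0.0,
    biases: Sequence[str] = ("deep", "none", "recent"),
) -> tuple[AlignedSequenceSet, SurveyChecklist, dict]:
    """Three floras drawn from one species pool, with divergence bias.

    ``biases`` picks each flora's species from a shared Yule pool: ``deep``
    prefers tips with the largest nearest-neighbour patristic distance (an
    isolated, immigrant-assembled island flora), ``recent`` prefers shallow
    cherry pairs (a continental flora with much in-situ speciation) and
    ``none`` samples at random.  ``shared_fraction`` of each flora's species
    are common to all three.  Designated failure pairs (per config) are
    injected among each flora's private species; additional zero distances
    arising naturally from recent splits are allowed — they are the signal
    the island/continental contrast is about.
    """
    if len(cfgs) != 3 or len(biases) != 3:
        raise ValueError("exactly three configs and three biases required")
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0, 1]")
    if len({c.seq_length for c in cfgs}) != 1:
        raise ValueError("all three configs must share seq_length")
    labels = [c.flora for c in cfgs]
    if len(set(labels)) != 3:
        raise ValueError("flora labels must be distinct")

    rng = np.random.default_rng(cfgs[0].seed)
    n_shared = int(round(shared_fraction * min(c.n_species for c in cfgs)))
    n_private = [c.n_species - n_shared for c in cfgs]
    pool = max(2 * (n_shared + sum(n_private)), 8)
    root, _ = _yule_tree(rng, pool, cfgs[0].birth_rate, cfgs[0].subst_rate)
    haplo = _evolve_jc(rng, root, cfgs[0].seq_length, pool)
    nn = _nearest_neighbor_distances(root, pool)

    names = [f"Taxon sp{i + 1:04d}" for i in range(pool)]
    unused = list(range(pool))
    shared = [
        int(i)
        for i in rng.choice(pool, size=n_shared, replace=False)
    ]
    unused = [i for i in unused if i not in set(shared)]

    flora_species: dict[str, list[int]] = {}
    for cfg, bias, need in zip(cfgs, biases, n_private):
        if bias == "deep":
            order = sorted(unused, key=lambda i: -nn[i])
            picked = order[:need]
        elif bias == "recent":
            order = sorted(unused, key=lambda i: nn[i])
            picked = order[:need]
        elif bias == "none":
            picked = [
                int(i)
                for i in rng.choice(len(unused), size=need, replace=False)
            ]
            picked = [unused[k] for k in picked]
        else:
            raise ValueError(f"unknown bias {bias!r}")
        flora_species[cfg.flora] = shared + picked
        unused = [i for i in unused if i not in set(picked)]

    # per-flora haplotypes: shared species keep the pool haplotype; failure
    # pairs are injected among private species only
    flora_haplo: dict[str, dict[int, np.ndarray]] = {}
    truth_failures: dict[str, list[list[str]]] = {}
    for cfg in cfgs:
        species = flora_species[cfg.flora]
        hmap = {i: haplo[i] for i in species}
        private = [i for i in species if i not in set(shared)]
        if 2 * cfg.n_failure_pairs > len(private):
            raise ValueError(
                f"flora {cfg.flora!r}: not enough private species for "
                f"{cfg.n_failure_pairs} failure pairs"
            )
        sel = rng.choice(
            len(private), size=2 * cfg.n_failure_pairs, replace=False
        )
        pairs = []
        for k in range(cfg.n_failure_pairs):
            a, b = private[int(sel[2 * k])], private[int(sel[2 * k + 1])]
            hmap[b] = hmap[a]
            pairs.append(sorted((names[a], names[b])))
        flora_haplo[cfg.flora] = hmap
        truth_failures[cfg.flora] = pairs

    specimen_ids: list[str] = []
    specimen_rows: list[str] = []
    specimen_map: dict[str, str] = {}
    specimen_flora: dict[str, str] = {}
    records: dict[str, TaxonRecord] = {}
    meta_cache: dict[int, tuple] = {}
    taxon_floras: dict[str, set[str]] = {}

    for cfg in cfgs:
        for i in flora_species[cfg.flora]:
            taxon_floras.setdefault(names[i], set()).add(cfg.flora)
            if i not in meta_cache:
                family = _FERN_FAMILIES[(i // 3) % len(_FERN_FAMILIES)]
                meta_cache[i] = (
                    f"{family[:4]}genus{(i // 3) + 1:02d}",
                    family,
                    _draw_habits(rng, cfg.habit_probs),
                )
            seq = flora_haplo[cfg.flora][i]
            if rng.random() < cfg.p_single_specimen:
                n_spec = 1
            else:
                n_spec = int(rng.integers(2, cfg.max_specimens + 1))
            for j in range(n_spec):
                s = seq.copy()
                if j > 0 and rng.random() < 0.5:
                    site = rng.integers(cfg.seq_length)
                    s[site] = (s[site] + rng.integers(1, 4)) % 4
                sid = f"{cfg.flora}-{i + 1:04d}-{j + 1}"
                specimen_ids.append(sid)
                specimen_rows.append(_decode(s))
                specimen_map[sid] = names[i]
                specimen_flora[sid] = cfg.flora

    for taxon, floras in taxon_floras.items():
        i = names.index(taxon)
        genus, family, habits = meta_cache[i]
        records[taxon] = TaxonRecord(
            name=taxon,
            rank="species",
            genus=genus,
            family=family,
            growth_habits=habits,
            native=True,
            floras=frozenset(floras),
        )

    aln = AlignedSequenceSet(tuple(specimen_ids), tuple(specimen_rows))
    checklist = SurveyChecklist(records, specimen_map, specimen_flora)
    truth = {
        "species_per_flora": {
            cfg.flora: sorted(names[i] for i in flora_species[cfg.flora])
            for cfg in cfgs
        },
        "shared_species": sorted(names[i] for i in shared),
        "failure_pairs_per_flora": truth_failures,
    }
    return aln, checklist, truth
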