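"""Synthetic data with known ground truth.

Emulated inputs: mutated protein families with correlated AA/3Di strings,
idealized C-alpha traces keyed to the 3Di letters, multi-domain
architectures with derivable hit tables, toy taxonomies and toy
Pfam/EC annotation tables.  Everything is deterministic given a seed, and
all generators emit exactly the dialects the I/O layer reads.

The mutation model: each site of a member is hit with probability equal to
the substitution rate; with probability ``coupling`` the AA and 3Di letters
share one mutation event (both resampled uniformly), otherwise the two
strings mutate independently at the same rate.  Structure is therefore as
conserved as sequence marginally, but co-varies with it — the regime the
structural clustering stage is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotate import AnnotationTable, PfamRegion
from .records import ALPHABET, Clustering, HitRecord, StructureRecord, StructureSet
from .taxonomy import TaxNode, Taxonomy

__all__ = [
    "FamilySpec",
    "GroundTruth",
    "simulate_family",
    "simulate_families",
    "simulate_coords",
    "default_domain_pool",
    "random_architectures",
    "simulate_multidomain",
    "simulate_domain_hits",
    "simulate_taxonomy",
    "simulate_annotations",
    "pairwise_family_metrics",
    "demo_families",
]


@dataclass
class FamilySpec:
    """Parameters of one simulated protein family."""

    family_id: str
    length: int = 200
    n_members: int = 10
    sub_rate: float = 0.15
    coupling: float = 0.8
    indel_rate: float = 0.0
    indel_mean: float = 3.0
    noise_sigma: float = 0.0  # coordinate noise amplitude, Angstrom

    def __post_init__(self) -> None:
        if not (0 <= self.sub_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("rates must be in [0, 1)")
        if self.length < 30:
            raise ValueError("family length must be >= 30")


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated structure set."""

    member_family: dict[str, str] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)
    domains: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    taxids: dict[str, int] = field(default_factory=dict)

    def update(self, other: "GroundTruth") -> None:
        self.member_family.update(other.member_family)
        self.lengths.update(other.lengths)
        self.domains.update(other.domains)
        self.taxids.update(other.taxids)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def _mutate_pair(aa: str, tdi: str, spec: FamilySpec,
                 rng: np.random.Generator) -> tuple[str, str]:
    L = len(aa)
    shared = rng.random(L) < spec.coupling
    hit_common = rng.random(L) < spec.sub_rate
    hit_aa = np.where(shared, hit_common, rng.random(L) < spec.sub_rate)
    hit_tdi = np.where(shared, hit_common, rng.random(L) < spec.sub_rate)
    aa_new = list(aa)
    tdi_new = list(tdi)
    for i in range(L):
        if hit_aa[i]:
            aa_new[i] = ALPHABET[rng.integers(len(ALPHABET))]
        if hit_tdi[i]:
            tdi_new[i] = ALPHABET[rng.integers(len(ALPHABET))]
    if spec.indel_rate > 0:
        aa_out, tdi_out = [], []
        i = 0
        while i < L:
            r = rng.random()
            if r < spec.indel_rate / 2:  # deletion
                i += 1 + rng.geometric(1.0 / spec.indel_mean)
                continue
            if r < spec.indel_rate:      # insertion
                n_ins = 1 + rng.geometric(1.0 / spec.indel_mean)
                for _ in range(n_ins):
                    aa_out.append(ALPHABET[rng.integers(len(ALPHABET))])
                    tdi_out.append(ALPHABET[rng.integers(len(ALPHABET))])
            aa_out.append(aa_new[i])
            tdi_out.append(tdi_new[i])
            i += 1
        aa_new, tdi_new = aa_out, tdi_out
    return "".join(aa_new), "".join(tdi_new)


# --- idealized C-alpha geometry ------------------------------------------

CA_SPACING = 3.8  # Angstrom between consecutive C-alpha positions

# Fixed letter -> (bond angle, dihedral) map; drawn once from a pinned
# generator so paths from different random 3Di strings diverge quickly.
_geom_rng = np.random.default_rng(987654321)
_THETA = np.deg2rad(_geom_rng.uniform(55.0, 145.0, size=len(ALPHABET)))
_PHI = np.deg2rad(_geom_rng.uniform(-180.0, 180.0, size=len(ALPHABET)))
del _geom_rng

_NOISE_WINDOW = 5  # chain smoothing window for coordinate noise


def _place_next(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                r: float, theta: float, phi: float) -> np.ndarray:
    """NeRF point placement from three predecessors + internal coordinates."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        # collinear predecessors: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, helper)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    d = np.array([-r * np.cos(theta),
                  r * np.sin(theta) * np.cos(phi),
                  r * np.sin(theta) * np.sin(phi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _path_from_tdi(tdi: str) -> np.ndarray:
    """Idealized C-alpha trace: 3.8 A steps, geometry keyed to 3Di letters."""
    L = len(tdi)
    coords = np.zeros((L, 3))
    if L > 1:
        coords[1] = [CA_SPACING, 0.0, 0.0]
    if L > 2:
        coords[2] = coords[1] + CA_SPACING * np.array(
            [np.cos(np.deg2rad(60)), np.sin(np.deg2rad(60)), 0.0])
    idx = [ALPHABET.index(c) if c in ALPHABET else 0 for c in tdi]
    for i in range(3, L):
        coords[i] = _place_next(coords[i - 3], coords[i - 2], coords[i - 1],
                                CA_SPACING, _THETA[idx[i]], _PHI[idx[i]])
    return coords


def _smooth_noise(L: int, sigma: float, rng: np.random.Generator
                  ) -> np.ndarray:
    """Chain-correlated displacement field (moving average of white noise).

    Smoothing makes nearby residues move together, mimicking the rigid-ish
    local perturbations of real conformational noise rather than
    independent per-atom jitter; ``sigma`` is the amplitude of the
    underlying white field, so the marginal per-residue displacement is
    smaller by ~1/sqrt(window).
    """
    if sigma == 0:
        return np.zeros((L, 3))
    raw = rng.normal(0.0, sigma, size=(L + _NOISE_WINDOW - 1, 3))
    kernel = np.ones(_NOISE_WINDOW) / _NOISE_WINDOW
    out = np.empty((L, 3))
    for d in range(3):
        out[:, d] = np.convolve(raw[:, d], kernel, mode="valid")
    return out


def simulate_coords(record: StructureRecord, seed: int,
                    noise_sigma: float = 0.0,
                    ancestor_path: Optional[np.ndarray] = None) -> np.ndarray:
    """C-alpha coordinates for a record: shared family path plus noise.

    When ``ancestor_path`` is given (the family's ancestor trace) and has
    the record's length, the member's coordinates are that path plus a
    smooth noise field — so within-family structural similarity is high by
    construction.  Otherwise the path is rebuilt from the record's own 3Di
    string.
    """
    rng = np.random.default_rng(seed)
    if ancestor_path is not None and len(ancestor_path) == len(record):
        path = ancestor_path
    else:
        path = _path_from_tdi(record.tdi_seq)
    return path + _smooth_noise(len(record), noise_sigma, rng)


def simulate_family(spec: FamilySpec, seed: int,
                    with_coords: bool = False
                    ) -> tuple[StructureSet, GroundTruth]:
    """Simulate one family: ancestor plus mutated members."""
    rng = np.random.default_rng(seed)
    aa_anc = _random_seq(rng, spec.length)
    tdi_anc = _random_seq(rng, spec.length)
    path = _path_from_tdi(tdi_anc) if with_coords else None
    records = []
    truth = GroundTruth()
    for j in range(spec.n_members):
        rid = f"{spec.family_id}_m{j}"
        aa, tdi = _mutate_pair(aa_anc, tdi_anc, spec, rng)
        coords = None
        if with_coords:
            coords = simulate_coords(
                StructureRecord(rid, aa, tdi),
                seed=int(rng.integers(2**31)),
                noise_sigma=spec.noise_sigma,
                ancestor_path=path,
            )
        plddt = np.full(len(aa), float(rng.uniform(55.0, 95.0)))
        records.append(StructureRecord(rid, aa, tdi, coords=coords,
                                       plddt=plddt))
        truth.member_family[rid] = spec.family_id
        truth.lengths[rid] = len(aa)
    return StructureSet(records), truth


def simulate_families(specs: Sequence[FamilySpec], seed: int,
                      with_coords: bool = False
                      ) -> tuple[StructureSet, GroundTruth]:
    """Simulate several families into one set (sub-seeded per family)."""
    rng = np.random.default_rng(seed)
    sset = StructureSet()
    truth = GroundTruth()
    for spec in specs:
        fam_set, fam_truth = simulate_family(
            spec, seed=int(rng.integers(2**31)), with_coords=with_coords)
        for rec in fam_set:
            sset.add(rec)
        truth.update(fam_truth)
    return sset, truth


def demo_families(n_families: int = 20, n_members: int = 10,
                  length: int = 200, sub_rate: float = 0.15,
                  seed: int = 42, with_coords: bool = False,
                  noise_sigma: float = 1.0
                  ) -> tuple[StructureSet, GroundTruth]:
    """The benchmark fixture: 20 families x 10 members at L=200."""
    specs = [
        FamilySpec(family_id=f"F{k:02d}", length=length, n_members=n_members,
                   sub_rate=sub_rate, noise_sigma=noise_sigma)
        for k in range(n_families)
    ]
    return simulate_families(specs, seed=seed, with_coords=with_coords)


# --- multi-domain architectures ------------------------------------------


def default_domain_pool(n_families: int = 5, length: int = 200,
                        seed: int = 0) -> dict[str, tuple[str, str]]:
    """Ancestral (AA, 3Di) segments for a pool of domain families.

    200 residues is a typical Pfam-domain scale; it also keeps adjacent
    domains on one protein well separated in (start, end) space relative
    to the boundary-clustering tree cut.
    """
    rng = np.random.default_rng(seed)
    return {f"D{k}": (_random_seq(rng, length), _random_seq(rng, length))
            for k in range(n_families)}


def random_architectures(family_pool: dict[str, tuple[str, str]],
                         n_proteins: int, seed: int,
                         max_domains: int = 3) -> list[list[str]]:
    """Random shuffled architectures of 1..max_domains pool families."""
    rng = np.random.default_rng(seed)
    fams = sorted(family_pool)
    return [
        [fams[int(rng.integers(len(fams)))]
         for _ in range(int(rng.integers(1, max_domains + 1)))]
        for _ in range(n_proteins)
    ]


def simulate_multidomain(family_pool: dict[str, tuple[str, str]],
                         architectures: Sequence[Sequence[str]],
                         seed: int, sub_rate: float = 0.1,
                         coupling: float = 0.8,
                         linker_range: tuple[int, int] = (5, 20)
                         ) -> tuple[StructureSet, GroundTruth]:
    """Concatenate mutated family segments into multi-domain proteins.

    ``family_pool`` maps a domain-family id to its ancestral (AA, 3Di)
    segment pair; each architecture (a list of family ids) yields one
    protein with 5-20 residue random linkers between segments.  Planted
    domain intervals are recorded in the ground truth.
    """
    rng = np.random.default_rng(seed)
    sset = StructureSet()
    truth = GroundTruth()
    for p, arch in enumerate(architectures):
        pid = f"P{p:03d}"
        aa_parts: list[str] = []
        tdi_parts: list[str] = []
        intervals: list[tuple[str, int, int]] = []
        pos = 0
        for d, fam in enumerate(arch):
            if d > 0:
                linker = int(rng.integers(linker_range[0],
                                          linker_range[1] + 1))
                aa_parts.append(_random_seq(rng, linker))
                tdi_parts.append(_random_seq(rng, linker))
                pos += linker
            aa_anc, tdi_anc = family_pool[fam]
            spec = FamilySpec(family_id=fam, length=max(len(aa_anc), 30),
                              sub_rate=sub_rate, coupling=coupling)
            aa_seg, tdi_seg = _mutate_pair(aa_anc, tdi_anc, spec, rng)
            aa_parts.append(aa_seg)
            tdi_parts.append(tdi_seg)
            intervals.append((fam, pos, pos + len(aa_seg)))
            pos += len(aa_seg)
        aa = "".join(aa_parts)
        tdi = "".join(tdi_parts)
        sset.add(StructureRecord(pid, aa, tdi))
        truth.domains[pid] = intervals
        truth.lengths[pid] = len(aa)
    return sset, truth


def simulate_domain_hits(truth: GroundTruth, seed: int,
                         evalue: float = 1e-8, jitter_sd: float = 5.0,
                         remote_pairs: Sequence[tuple[str, str, float]] = ()
                         ) -> list[HitRecord]:
    """Derive a pairwise hit table from planted domain intervals.

    Every pair of instances of the same family on different proteins
    yields hits in both directions, with boundaries jittered by a Gaussian
    of ``jitter_sd`` residues.  ``remote_pairs`` plants one weaker
    inter-family hit per (family_a, family_b, evalue) triple, emulating a
    remote structural similarity between distinct families.
    """
    rng = np.random.default_rng(seed)
    instances: dict[str, list[tuple[str, int, int]]] = {}
    for pid, intervals in truth.domains.items():
        for fam, start, end in intervals:
            instances.setdefault(fam, []).append((pid, start, end))

    def jitter(start: int, end: int, length: int) -> tuple[int, int]:
        s = int(round(start + rng.normal(0, jitter_sd)))
        e = int(round(end + rng.normal(0, jitter_sd)))
        s = max(0, min(s, length - 2))
        e = max(s + 1, min(e, length))
        return s, e

    hits: list[HitRecord] = []
    for fam, inst in instances.items():
        for i in range(len(inst)):
            for j in range(len(inst)):
                if i == j:
                    continue
                qpid, qs, qe = inst[i]
                tpid, ts, te = inst[j]
                if qpid == tpid:
                    continue
                qs_, qe_ = jitter(qs, qe, truth.lengths[qpid])
                ts_, te_ = jitter(ts, te, truth.lengths[tpid])
                e_val = evalue * 10 ** float(rng.normal(0, 1))
                hits.append(HitRecord(qpid, tpid, qs_, qe_, ts_, te_,
                                      score=100.0, evalue=e_val))
    for fam_a, fam_b, e_val in remote_pairs:
        # plant the remote similarity between instances on *different*
        # proteins: a same-protein hit would be discarded as a self-hit
        planted = False
        for qpid, qs, qe in instances[fam_a]:
            for tpid, ts, te in instances[fam_b]:
                if qpid != tpid:
                    hits.append(HitRecord(qpid, tpid, qs, qe, ts, te,
                                          score=30.0, evalue=e_val))
                    planted = True
                    break
            if planted:
                break
        if not planted:
            raise ValueError(
                f"families {fam_a!r} and {fam_b!r} never co-occur on "
                "distinct proteins; cannot plant a remote link")
    return hits


# --- taxonomy --------------------------------------------------------------

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus",
         "species")


def simulate_taxonomy(n_leaves: int, depth: int = 7, seed: int = 0,
                      include_ignored: bool = False
                      ) -> tuple[Taxonomy, list[int]]:
    """Random rooted taxonomy with standard rank labels.

    Returns the taxonomy and the list of leaf taxids (rank = deepest rank
    used).  With ``include_ignored`` the two conventional "unclassified /
    other sequences" subtrees (taxids 12908 and 28384) are attached below
    the root, each with one plantable leaf child.
    """
    if not (1 <= depth <= len(RANKS)):
        raise ValueError(f"depth must be in 1..{len(RANKS)}")
    rng = np.random.default_rng(seed)
    nodes: dict[int, TaxNode] = {1: TaxNode(1, 1, "no rank", "root")}
    next_id = 2
    ranks = RANKS[:depth]

    def new_node(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        while next_id in (12908, 28384):
            next_id += 1
        nodes[next_id] = TaxNode(next_id, parent, rank, name)
        next_id += 1
        return next_id - 1

    def grow(parent: int, level: int, n: int) -> list[int]:
        """Attach a subtree with n leaves below parent; return leaf ids."""
        rank = ranks[level]
        if level == len(ranks) - 1:
            return [new_node(parent, rank, f"{rank}_{new_id}")
                    for new_id in range(n)]
        k = int(rng.integers(1, min(3, n) + 1))
        split = sorted(rng.choice(np.arange(1, n), size=k - 1,
                                  replace=False)) if k > 1 else []
        sizes = np.diff([0, *split, n])
        leaves = []
        for size in sizes:
            child = new_node(parent, rank, f"{rank}_{parent}_{len(leaves)}")
            leaves.extend(grow(child, level + 1, int(size)))
        return leaves

    leaves = grow(1, 0, n_leaves)
    if include_ignored:
        for special in (12908, 28384):
            nodes[special] = TaxNode(special, 1, "no rank",
                                     f"pseudo_{special}")
            nodes[special * 10] = TaxNode(special * 10, special, "species",
                                          f"pseudo_leaf_{special}")
    return Taxonomy(nodes, root=1), leaves


# --- annotations ------------------------------------------------------------


def simulate_annotations(truth: GroundTruth, noise: float, seed: int
                         ) -> AnnotationTable:
    """Planted Pfam/clan and EC annotations with two-label flip noise.

    Each family has one planted clan and one decoy clan; a member carries
    the decoy with probability ``noise``, the planted label otherwise.
    Because noise flips between exactly two labels, the expected pairwise
    consistency of a two-member cluster is (1-noise)^2 + noise^2 — 0.5 at
    50% noise, which the consistency metrics can be checked against in
    closed form.  ECs follow the same flip model with the decoy differing
    at the top EC class (hence at every level).
    """
    rng = np.random.default_rng(seed)
    families = sorted(set(truth.member_family.values()))
    planted_clan = {f: f"CL{k:04d}" for k, f in enumerate(families)}
    decoy_clan = {f: f"CL9{k:03d}" for k, f in enumerate(families)}
    planted_acc = {f: f"PF{k:05d}" for k, f in enumerate(families)}
    decoy_acc = {f: f"PF9{k:04d}" for k, f in enumerate(families)}
    planted_ec = {f: f"{k % 6 + 1}.{k % 9 + 1}.{k % 20 + 1}.{k + 1}"
                  for k, f in enumerate(families)}
    decoy_ec = {f: f"{(k + 3) % 6 + 1}.{k % 9 + 1}.{k % 20 + 1}.{k + 1}"
                for k, f in enumerate(families)}
    table = AnnotationTable()
    for mid, fam in truth.member_family.items():
        flip = rng.random() < noise
        clan = decoy_clan[fam] if flip else planted_clan[fam]
        acc = decoy_acc[fam] if flip else planted_acc[fam]
        length = truth.lengths[mid]
        table.pfam[mid] = [PfamRegion(acc, clan, 0, length)]
        flip_ec = rng.random() < noise
        table.ec[mid] = [decoy_ec[fam] if flip_ec else planted_ec[fam]]
    return table


# --- evaluation helpers -----------------------------------------------------


def pairwise_family_metrics(clustering: Clustering,
                            member_family: dict[str, str]
                            ) -> tuple[float, float]:
    """Pairwise precision and recall of a clustering vs planted families.

    A pair of members is positive when it is co-clustered; true when the
    two members share a planted family.
    """
    ids = [i for i in clustering.members if i in member_family]
    tp = fp = fn = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            same_truth = member_family[ids[i]] == member_family[ids[j]]
            same_clust = clustering.co_clustered(ids[i], ids[j])
            if same_clust and same_truth:
                tp += 1
            elif same_clust and not same_truth:
                fp += 1
            elif same_truth and not same_clust:
                fn += 1
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return precision, recall
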