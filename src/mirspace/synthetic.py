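"""Synthetic input bundles with planted cluster and paralog-group structure.

The generator partitions miRNAs and diseases into clusters and makes every
information channel cluster-coherent: abstracts draw from a cluster
vocabulary, targets come from a cluster gene pool, families are
cluster-specific, cluster members are co-located on one synthetic chromosome
and a MeSH-like tree places same-cluster diseases under a common subtree (so
Lin similarity is informative).

Within each cluster, miRNAs form paralog groups (default size 5) that mimic
genomic miRNA clusters: group members sit a few kb apart, share one family
and one disjoint target repertoire, and acquire disease associations as a
group (co-regulated paralogs tend to share disease involvement). Group
diseases are dealt so each group's count matches the nominal association
density and per-disease coverage stays even.

The withheld ground-truth pairs take one member per group disease: the
masked miRNA's four paralogs keep the association, so a masked pair is
recoverable from the data — mirroring how curated databases lag behind the
literature for members of known miRNA clusters. With group size 5 the
withheld share of the association table is one fifth, exactly the default
masking fraction. A retained association enjoys one fewer supporting paralog
during held-out scoring (the held-out miRNA itself no longer supports it),
which is the asymmetry the recovery tests exercise.

Everything is deterministic given the seed; same seed, byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from . import io

__all__ = ["GeneratorParams", "Bundle", "generate", "fig3_fixture"]


def _alpha(index: int, width: int = 3) -> str:
    """Deterministic lowercase-letter encoding of an integer (>= 3 chars)."""
    letters = []
    index = int(index)
    while index or len(letters) < width:
        letters.append(chr(ord("a") + index % 26))
        index //= 26
    return "".join(reversed(letters))


@dataclass
class GeneratorParams:
    n_mirnas: int = 200
    n_diseases: int = 30
    n_targets: int = 120
    n_families: int = 10
    n_words: int = 400
    n_clusters: int = 5
    assoc_density: float = 0.6
    cross_cluster_noise: float = 0.02
    masking_fraction: float = 0.2
    seed: int = 0
    #: paralog-group size (genomic miRNA clusters of co-regulated members);
    #: with one member withheld per group disease, the withheld share of the
    #: association table is 1/group_size, matching masking_fraction = 0.2
    group_size: int = 5
    #: fraction of each cluster's miRNAs living in paralog groups; the rest
    #: are loners whose associations are individual
    grouped_fraction: float = 1.0
    word_purity: float = 0.8
    abstract_length: int = 80
    #: upper bound on repertoire size; the effective size also keeps the
    #: per-cluster gene pool large enough for disjoint group repertoires
    targets_per_mirna: int = 12
    #: gap between paralogs inside a group / between groups / between loners,
    #: in bp; groups sit well beyond the coexpression range so proximity marks
    #: group mates, while loners are spaced so their neighborhood mass matches
    #: a group member's
    intra_group_gap_bp: tuple[int, int] = (5_000, 8_000)
    gap_range_bp: tuple[int, int] = (150_000, 250_000)
    loner_gap_bp: tuple[int, int] = (30_000, 40_000)

    def validate(self) -> None:
        if self.n_clusters > min(self.n_mirnas, self.n_diseases):
            raise ValueError("n_clusters must not exceed min(n_mirnas, n_diseases)")
        for name in ("assoc_density", "cross_cluster_noise", "masking_fraction",
                     "word_purity"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if min(self.n_mirnas, self.n_diseases, self.n_targets, self.n_families,
               self.n_words, self.n_clusters, self.group_size) < 1:
            raise ValueError("all sizes must be positive")
        if self.n_mirnas // self.n_clusters < self.group_size:
            raise ValueError("infeasible cluster sizes: clusters smaller than one group")


@dataclass
class Bundle:
    directory: Path
    params: GeneratorParams
    mirna_cluster: dict[str, int]
    disease_cluster: dict[str, int]
    masked_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def paths(self) -> dict[str, Path]:
        return {key: self.directory / name for key, name in io.BUNDLE_FILES.items()}

    @property
    def truth_path(self) -> Path:
        return self.directory / "truth.tsv"


def _cluster_of(index: int, total: int, n_clusters: int) -> int:
    return index * n_clusters // total


def generate(params: GeneratorParams, directory: str | Path) -> Bundle:
    """Write a complete input bundle (all six formats plus the truth file)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    mirnas = [f"mir-{i:04d}" for i in range(params.n_mirnas)]
    diseases = [f"d{_cluster_of(j, params.n_diseases, params.n_clusters):02d}x{j:03d}"
                for j in range(params.n_diseases)]
    mirna_cluster = {m: _cluster_of(i, params.n_mirnas, params.n_clusters)
                     for i, m in enumerate(mirnas)}
    disease_cluster = {d: _cluster_of(j, params.n_diseases, params.n_clusters)
                       for j, d in enumerate(diseases)}
    by_cluster_m: dict[int, list[str]] = {}
    for m in mirnas:
        by_cluster_m.setdefault(mirna_cluster[m], []).append(m)
    by_cluster_d: dict[int, list[str]] = {}
    for d in diseases:
        by_cluster_d.setdefault(disease_cluster[d], []).append(d)

    # --- paralog groups and loners ----------------------------------------
    groups: list[list[str]] = []
    group_of: dict[str, int] = {}
    for k in sorted(by_cluster_m):
        members = by_cluster_m[k]
        n_grouped = int(params.grouped_fraction * len(members) / params.group_size)
        n_grouped *= params.group_size
        chunks = [
            members[start:start + params.group_size]
            for start in range(0, n_grouped, params.group_size)
        ] + [[m] for m in members[n_grouped:]]
        for chunk in chunks:
            for m in chunk:
                group_of[m] = len(groups)
            groups.append(chunk)

    # --- associations: balanced group-level patterns ----------------------
    # each full group carries a handful of "group diseases" (every member
    # associated — co-regulated paralogs) plus "single" associations of
    # individual members; counts alternate so the marginal per-cell
    # probability stays close to assoc_density and per-disease coverage is
    # even. One member of each group disease is later withheld, which makes
    # the withheld fraction land on masking_fraction by construction.
    g = params.group_size
    associations: dict[str, set[str]] = {m: set() for m in mirnas}
    group_disease_members: dict[tuple[int, str], list[str]] = {}
    gd_count: dict[str, int] = {d: 0 for d in diseases}
    single_count: dict[str, int] = {d: 0 for d in diseases}
    for gi, members in enumerate(groups):
        k = mirna_cluster[members[0]]
        local = by_cluster_d[k]
        # per-row budget ~ density * #cluster diseases, alternating rounding
        budget = len(local) * params.assoc_density
        n_ds = int(np.floor(budget)) + (1 if gi % 2 and budget % 1 else 0)
        n_ds = max(1, min(n_ds, len(local)))
        if len(members) == g:
            # paralog group: all members share every chosen disease
            order = sorted(local, key=lambda d: (gd_count[d], rng.random()))
            for d in order[:n_ds]:
                gd_count[d] += 1
                for m in members:
                    associations[m].add(d)
                group_disease_members[(gi, d)] = list(members)
        else:
            # loners: individual associations
            for m in members:
                order = sorted(local, key=lambda d: (single_count[d], rng.random()))
                for d in order[:n_ds]:
                    single_count[d] += 1
                    associations[m].add(d)
    # cross-cluster noise is also group-structured (a whole paralog group
    # acquires a foreign disease), keeping the per-pair rate at the nominal
    # noise level while staying consistent with the group model
    for gi, members in enumerate(groups):
        k = mirna_cluster[members[0]]
        for d in diseases:
            if disease_cluster[d] != k and rng.random() < params.cross_cluster_noise:
                for m in members:
                    associations[m].add(d)
                if len(members) == g:
                    group_disease_members[(gi, d)] = list(members)

    # --- masking: withhold members of group diseases, round by round ------
    # each group disease keeps at least one carrier; victims rotate within a
    # group so masking spreads evenly across paralogs
    total_true = sum(len(v) for v in associations.values())
    n_mask = int(round(params.masking_fraction * total_true))
    candidates = sorted(group_disease_members)
    rng.shuffle(candidates)
    queues: list[list[tuple[str, str]]] = []
    turn: dict[int, int] = {}
    for gi, d in candidates:
        members = group_disease_members[(gi, d)]
        start = turn.get(gi, 0)
        turn[gi] = start + 1
        queues.append(
            [(members[(start + j) % len(members)], d) for j in range(len(members) - 1)]
        )
    masked: list[tuple[str, str]] = []
    for round_no in range(max((len(q) for q in queues), default=0)):
        for queue in queues:
            if len(masked) >= n_mask:
                break
            if round_no < len(queue):
                masked.append(queue[round_no])
        if len(masked) >= n_mask:
            break
    true_associations = {m: set(ds) for m, ds in associations.items()}
    for m, d in masked:
        associations[m].discard(d)
    masked_set = set(masked)

    # --- targets: disjoint repertoires for paralog groups -----------------
    # each full group owns a private slice of the cluster pool (paralogs share
    # seed sequence, hence targets); loners sample from the leftover genes
    genes = [f"gene{_alpha(t)}" for t in range(params.n_targets)]
    pool_size = params.n_targets // params.n_clusters
    full_by_cluster: dict[int, list[int]] = {}
    for gi, members in enumerate(groups):
        if len(members) == g:
            full_by_cluster.setdefault(mirna_cluster[members[0]], []).append(gi)
    targets: dict[str, set[str]] = {}
    for k in sorted(by_cluster_m):
        pool = genes[k * pool_size:(k + 1) * pool_size]
        full = full_by_cluster.get(k, [])
        per = min(params.targets_per_mirna, max(1, pool_size // (len(full) + 2)))
        for slot, gi in enumerate(full):
            lo = (slot * per) % max(1, pool_size - per + 1)
            repertoire = set(pool[lo:lo + per])
            for m in groups[gi]:
                targets[m] = set(repertoire)
        leftover = pool[len(full) * per:] or pool
        for gi, members in enumerate(groups):
            if mirna_cluster[members[0]] != k or len(members) == g:
                continue
            size = min(per, len(leftover))
            picks = rng.choice(len(leftover), size=size, replace=False)
            targets[members[0]] = {leftover[int(t)] for t in picks}

    # --- families: one per group, cycled so same-cluster groups differ ----
    fams = [f"fam{_alpha(f)}" for f in range(params.n_families)]
    families: dict[str, str] = {}
    for gi, members in enumerate(groups):
        fam = fams[gi % params.n_families]
        for m in members:
            families[m] = fam

    # --- abstracts: cluster vocabulary with background noise --------------
    n_cluster_words = max(1, int(0.7 * params.n_words) // params.n_clusters)
    n_background = max(1, params.n_words - n_cluster_words * params.n_clusters)
    cluster_vocab = {
        k: [f"c{k}{_alpha(w)}" for w in range(n_cluster_words)]
        for k in range(params.n_clusters)
    }
    background = [f"bg{_alpha(w)}" for w in range(n_background)]
    abstracts: dict[str, str] = {}
    for m in mirnas:
        k = mirna_cluster[m]
        tokens = [
            (cluster_vocab[k][int(rng.integers(n_cluster_words))]
             if rng.random() < params.word_purity
             else background[int(rng.integers(n_background))])
            for _ in range(params.abstract_length)
        ]
        abstracts[m] = " ".join(tokens)

    # --- genomic layout: groups are tight runs on the cluster chromosome --
    locations: dict[str, list[io.Location]] = {}
    cursor: dict[int, int] = {}
    previous_single: dict[int, bool] = {}
    glow, ghigh = params.gap_range_bp
    ilow, ihigh = params.intra_group_gap_bp
    llow, lhigh = params.loner_gap_bp
    for members in groups:
        k = mirna_cluster[members[0]]
        single = len(members) == 1
        if single and previous_single.get(k):
            gap = int(rng.integers(llow, lhigh + 1))
        else:
            gap = int(rng.integers(glow, ghigh + 1))
        previous_single[k] = single
        cursor[k] = cursor.get(k, 10_000) + gap
        for j, m in enumerate(members):
            if j:
                cursor[k] += int(rng.integers(ilow, ihigh + 1))
            length = int(rng.integers(80, 121))
            strand = "+" if rng.random() < 0.5 else "-"
            locations[m] = [(f"chr{k + 1}", strand, cursor[k], cursor[k] + length - 1)]
            cursor[k] += length

    # --- disease tree: per-cluster subtree, diseases paired under subgroups
    tree: dict[str, set[str]] = {}
    for k in range(params.n_clusters):
        top = f"C{k + 1:02d}"
        tree[f"group{k:02d}"] = {top}
        for j, d in enumerate(by_cluster_d[k]):
            sub = j // 2
            tree[f"group{k:02d}s{sub:02d}"] = {f"{top}.{(sub + 1) * 100:03d}"}
            tree[d] = {f"{top}.{(sub + 1) * 100:03d}.{(j % 2 + 1) * 10:03d}"}

    # --- write everything -------------------------------------------------
    pmids = {
        (m, d): str(10_000_000 + idx)
        for idx, (m, d) in enumerate(
            (m, d) for m in sorted(associations) for d in sorted(associations[m])
        )
    }
    files = io.BUNDLE_FILES
    io.write_associations(associations, directory / files["associations"], pmids)
    io.write_locations(locations, directory / files["locations"])
    io.write_families(families, directory / files["families"])
    io.write_abstracts(abstracts, directory / files["abstracts"])
    io.write_targets(targets, directory / files["targets"])
    io.write_tree(tree, directory / files["tree"])

    bundle = Bundle(
        directory=directory,
        params=params,
        mirna_cluster=mirna_cluster,
        disease_cluster=disease_cluster,
        masked_pairs=sorted(masked),
    )
    with open(bundle.truth_path, "w", encoding="utf-8") as fh:
        fh.write("# withheld mirna\tdisease pairs\n")
        for m, d in bundle.masked_pairs:
            fh.write(f"{m}\t{d}\n")
    return bundle


def fig3_fixture() -> tuple[sp.csr_matrix, list[str], list[str]]:
    """The 4-miRNA x 4-target toy bipartite graph used by the projection tests.

    Text-constrained edges: a-alpha; b-alpha, b-beta; beta has degree 3.
    The remaining attachments (gamma, delta) are one arbitrary completion
    (c-beta, c-gamma; d-beta, d-delta); tests rely only on the constrained
    quantities.
    """
    mirnas = ["a", "b", "c", "d"]
    targets = ["alpha", "beta", "gamma", "delta"]
    edges = [(0, 0), (1, 0), (1, 1), (2, 1), (2, 2), (3, 1), (3, 3)]
    M = sp.lil_matrix((4, 4))
    for i, j in edges:
        M[i, j] = 1.0
    return M.tocsr(), mirnas, targets
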