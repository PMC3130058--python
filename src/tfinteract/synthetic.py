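"""Synthetic study generator with planted, known-ground-truth class signal.

The generator emits exactly the package's own input formats — a property
table in AAIndex1 dialect, protein sequences in FASTA, and a labelled pair
TSV — together with a ground-truth JSON naming the pair-vector features
that carry class signal.  It is the package's test bed: a miniature
interaction study in which we know which features matter and by how much.

Design: the signal is planted at the residue-composition level, not by
emitting feature vectors directly, so that every downstream stage (FASTA
parsing, segmentation, property averaging, canonical pair ordering) is
exercised.  Proteins fall into three pools:

* ``A`` — interaction-prone proteins; positive pairs are drawn among them
  and their compositions are tilted along per-property directions built
  from the informative property scales, with random per-protein weights.
* ``B`` — promiscuous proteins that interact with external (non-study)
  partners only; they populate the hardest negative class.
* ``C`` — proteins with no known partners.

Negatives then follow the three standard classes: ``absolute`` = C x C,
``partial`` = (A u B) x C, ``ppi`` = B x B.  A pair of two pool-A proteins
is by construction a true interaction in this synthetic world, so PPI
negatives never coincide with the positive signal; partial negatives may
still contain one tilted protein, which keeps the learning problem
non-degenerate (a classifier restricted to one member's features cannot
separate those negatives from true pairs).

The tilt emulates a central interaction domain: it is confined to the mid
section of the sequence, so the signal-bearing features are the two
members' mid-segment means of the informative properties.  Its strength is
calibrated on the pair-level mean of each informative property over the
mid section (averaged over the two members): every informative property
separates positives from negatives by at least ``effect_size`` standard
deviations of the pure within-class noise, with the weakest property
sitting exactly at the target.  Every tilt direction
is orthogonal to the non-informative scales (and the composition simplex),
so non-informative features carry no first-order class signal; with
``effect_size = 0`` no tilt is applied at all.  All
randomness flows from one root seed through named substreams, and the
residue draws reuse one fixed set of uniforms across calibration steps, so
the whole study is a deterministic function of its spec.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .aaindex import (STANDARD_AA, PropertyEntry, PropertyTable,
                      filter_complete, parse_aaindex1, write_aaindex1)
from .dataset import InteractionRecord, InteractionSet
from .errors import FeasibilityError
from .features import ProteinRecord, compose_feature, FeatureTriple, \
    SEGMENT_NAMES, write_fasta
from . import dataset as _dataset

_ALPHABET22 = STANDARD_AA + "XU"

# Substream indices under the root SeedSequence.
_SS_PROPERTIES, _SS_POOLS, _SS_COMPOSITIONS, _SS_SEQUENCES = range(4)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic interaction data set.

    ``informative_properties`` uses 1-based property indices; ``None``
    (the default) lets the generator pick the ``n_informative`` scales of
    the drawn table that can be moved most independently of the others,
    which keeps the requested effect reachable whatever the table draw.
    ``effect_size`` is the planted class mean shift of each informative
    property's pair-level mid-section mean, in within-class standard
    deviations.

    The property table plays the role of external reference data (as the
    real amino-acid scale database does), so it has its own ``table_seed``
    rather than following the study seed: re-running a study with a new
    ``seed`` redraws proteins, pairs and sequence noise against the same
    scales, exactly as a real re-analysis would.
    """

    n_properties: int = 13
    n_tfs: int = 1000
    sequence_length_range: tuple[int, int] = (350, 750)
    n_positive: int = 200
    n_negative_per_class: int = 67
    informative_properties: tuple[int, ...] | None = None
    n_informative: int = 5
    effect_size: float = 2.5
    seed: int = 0
    table_seed: int = 0
    x_rate: float = 0.003
    u_rate: float = 0.001

    def __post_init__(self):
        lo, hi = self.sequence_length_range
        if lo < 5:
            raise ValueError("minimum sequence length must be >= 5")
        if lo > hi:
            raise ValueError("sequence_length_range must be (min, max)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.informative_properties is None:
            if not 1 <= self.n_informative <= self.n_properties:
                raise ValueError("n_informative out of range")
            return
        if not self.informative_properties:
            raise ValueError("informative_properties must be non-empty")
        bad = [p for p in self.informative_properties
               if not 1 <= p <= self.n_properties]
        if bad:
            raise ValueError(f"informative property indices out of range: {bad}")
        if len(set(self.informative_properties)) != len(self.informative_properties):
            raise ValueError("informative_properties contains duplicates")


@dataclass
class SyntheticStudy:
    """In-memory bundle of one generated study plus its ground truth."""

    spec: SyntheticSpec
    table: PropertyTable
    sequences: dict[str, ProteinRecord]
    interactions: InteractionSet
    known_partners: dict[str, set[str]]
    ground_truth: dict
    aaindex_text: str = ""

    def labels(self) -> list[str]:
        return [r.label for r in self.interactions.records]

    def pairs(self) -> list[tuple[str, str]]:
        return [(r.first_id, r.second_id) for r in self.interactions.records]

    def write(self, outdir) -> dict[str, str]:
        """Write sequences.fasta, properties.aaindex, pairs.tsv and
        ground_truth.json under ``outdir``; returns the path map."""
        import os
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "sequences.fasta"),
            "aaindex": os.path.join(outdir, "properties.aaindex"),
            "pairs": os.path.join(outdir, "pairs.tsv"),
            "ground_truth": os.path.join(outdir, "ground_truth.json"),
        }
        write_fasta(self.sequences.values(), paths["fasta"])
        with open(paths["aaindex"], "w") as fh:
            fh.write(self.aaindex_text or write_aaindex1(self.table))
        _dataset.write_pairs_tsv(self.interactions.records, paths["pairs"])
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth, fh, indent=1)
        return paths


def gen_property_table(n_properties: int, seed: int) -> PropertyTable:
    """Complete synthetic scales with values uniform in [-1, 1].

    Values are rounded to six decimals so the AAIndex1 text serialization
    round-trips bit-for-bit through :func:`parse_aaindex1`.
    """
    if n_properties < 1:
        raise ValueError("n_properties must be >= 1")
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_properties):
        vals = np.round(rng.uniform(-1.0, 1.0, 20), 6)
        entries.append(PropertyEntry(
            accession=f"SYN{i + 1:04d}",
            description=f"synthetic amino-acid scale {i + 1}",
            values={a: float(v) for a, v in zip(STANDARD_AA, vals)}))
    return PropertyTable(entries)


def gen_aaindex_file(n_entries: int, n_incomplete: int, seed: int) -> str:
    """AAIndex1 text with exactly ``n_incomplete`` records holding NA values."""
    if not 0 <= n_incomplete <= n_entries:
        raise ValueError("need 0 <= n_incomplete <= n_entries")
    rng = np.random.default_rng(seed)
    table = gen_property_table(n_entries, seed)
    entries = [PropertyEntry(e.accession, e.description, dict(e.values))
               for e in table.entries]
    which = rng.choice(n_entries, size=n_incomplete, replace=False)
    for idx in which:
        n_missing = int(rng.integers(1, 4))
        drop = rng.choice(20, size=n_missing, replace=False)
        for j in drop:
            entries[idx].values.pop(STANDARD_AA[j], None)
    return write_aaindex1(entries)


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------

def _joint_tilt_program(V: np.ndarray, inf0: list[int]
                        ) -> tuple[float, np.ndarray]:
    """Solve the shared-budget direction programme for a set of scales.

    Row j of the returned matrix is a residue-space direction that (i)
    lies on the composition simplex tangent (entries sum to zero), (ii)
    is invisible to every other scale of the table, and (iii) moves scale
    ``inf0[j]`` by exactly one unit.  Because the directions are mutually
    invisible, each informative property carries an independent component
    of the planted signal rather than a copy of one shared axis.

    The directions share the positivity budget, so a single linear
    programme maximises the worst scale's response subject to the *summed*
    tilt keeping every residue coordinate >= -1; the optimum (returned
    first) measures how large a planted shift the table geometry allows.
    """
    from scipy.optimize import linprog

    P = V.shape[0]
    k = len(inf0)
    bases: list[np.ndarray] = []
    for j in inf0:
        others = [V[i] for i in range(P) if i != j]
        constraints = np.vstack([np.ones(20)] + others)  # (m, 20)
        _, s, vt = np.linalg.svd(constraints)
        rank = int(np.sum(s > 1e-10))
        N = vt[rank:].T  # (20, f) null-space basis
        if N.shape[1] == 0:
            return 0.0, np.zeros((k, 20))
        bases.append(N)
    sizes = [N.shape[1] for N in bases]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    nvar = int(offs[-1]) + 1  # z blocks plus the maximin variable t
    A_ub = np.zeros((k + 20, nvar))
    b_ub = np.concatenate([np.zeros(k), np.ones(20)])
    for row, (j, N) in enumerate(zip(inf0, bases)):
        A_ub[row, offs[row]:offs[row + 1]] = -(V[j] @ N)
        A_ub[row, -1] = 1.0
        A_ub[k:, offs[row]:offs[row + 1]] = -N
    c = np.zeros(nvar)
    c[-1] = -1.0
    res = linprog(c, A_ub=A_ub, b_ub=b_ub,
                  bounds=[(None, None)] * nvar, method="highs")
    if not res.success or res.x[-1] <= 1e-9:
        return 0.0, np.zeros((k, 20))
    directions = np.zeros((k, 20))
    for row, (j, N) in enumerate(zip(inf0, bases)):
        g = N @ res.x[offs[row]:offs[row + 1]]
        directions[row] = g / float(V[j] @ g)  # unit response per scale
    return float(res.x[-1]), directions


def _signal_directions(table: PropertyTable, informative: tuple[int, ...]
                       ) -> np.ndarray:
    """Per-property tilt directions for a user-specified informative set."""
    if table.size + 1 > 19:
        raise FeasibilityError(
            "cannot decouple the tilt directions: need at most 18 scales "
            f"in total, have {table.size}")
    inf0 = [p - 1 for p in informative]
    optimum, directions = _joint_tilt_program(table.value_matrix(), inf0)
    if optimum <= 0.0:
        raise FeasibilityError(
            "informative scales cannot be moved independently of the "
            "other scales")
    return directions


def _select_informative(table: PropertyTable, k: int) -> tuple[int, ...]:
    """Pick the k scales whose joint planted shift can be largest (1-based).

    Greedy growth under the shared-budget programme: starting from the
    single scale with the best response, each step adds the scale that
    keeps the joint maximin response highest.  Scales nearly collinear
    with the rest of the table — or whose best directions fight over the
    same composition headroom — score low and are avoided, which keeps
    the requested effect size reachable for any table draw.
    """
    if table.size + 1 > 19:
        raise FeasibilityError(
            "cannot decouple the tilt directions: need at most 18 scales "
            f"in total, have {table.size}")
    V = table.value_matrix()
    chosen: list[int] = []
    for _ in range(k):
        best: tuple[float, int] | None = None
        for j in range(table.size):
            if j in chosen:
                continue
            optimum, _ = _joint_tilt_program(V, chosen + [j])
            if best is None or optimum > best[0]:
                best = (optimum, j)
        if best is None or best[0] <= 1e-9:
            raise FeasibilityError(
                "fewer than the requested number of scales can be moved "
                "independently of the rest of the table")
        chosen.append(best[1])
    return tuple(sorted(j + 1 for j in chosen))


def _sample_pairs(rng: np.random.Generator, candidates: list[tuple[str, str]],
                  n: int, what: str) -> list[tuple[str, str]]:
    if n > len(candidates):
        raise FeasibilityError(
            f"cannot draw {n} {what} pairs from {len(candidates)} candidates;"
            " increase n_tfs or reduce the request")
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx.tolist())]


def gen_interaction_study(spec: SyntheticSpec) -> SyntheticStudy:
    """Generate a full labelled study per the module docstring."""
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(4)
    table = gen_property_table(spec.n_properties, spec.table_seed)
    informative = (spec.informative_properties
                   if spec.informative_properties is not None
                   else _select_informative(table, spec.n_informative))

    ids = [f"TF{i + 1:04d}" for i in range(spec.n_tfs)]
    n_a = max(4, round(0.4 * spec.n_tfs))
    n_b = max(4, round(0.3 * spec.n_tfs))
    n_c = spec.n_tfs - n_a - n_b
    if n_c < 4:
        raise FeasibilityError(f"n_tfs={spec.n_tfs} is too small to "
                               "populate the three protein pools")
    pool_a, pool_b, pool_c = (ids[:n_a], ids[n_a:n_a + n_b],
                              ids[n_a + n_b:])

    rng_pool = np.random.default_rng(children[_SS_POOLS])
    import itertools
    positives = _sample_pairs(rng_pool,
                              list(itertools.combinations(pool_a, 2)),
                              spec.n_positive, "positive")
    known_partners: dict[str, set[str]] = {i: set() for i in ids}
    for k, pid in enumerate(pool_a + pool_b):
        known_partners[pid].add(f"XPROT{k + 1:04d}")  # external partner
    for a, b in positives:
        known_partners[a].add(b)
        known_partners[b].add(a)
    pos_keys = {frozenset(p) for p in positives}

    neg_pairs: dict[str, list[tuple[str, str]]] = {
        "absolute": _sample_pairs(
            rng_pool, list(itertools.combinations(pool_c, 2)),
            spec.n_negative_per_class, "absolute negative"),
        "partial": _sample_pairs(
            rng_pool, list(itertools.product(pool_a + pool_b, pool_c)),
            spec.n_negative_per_class, "partial negative"),
        "ppi": _sample_pairs(
            rng_pool, list(itertools.combinations(pool_b, 2)),
            spec.n_negative_per_class, "ppi negative"),
    }

    # Per-protein baseline compositions and one fixed set of uniforms; the
    # sequences are then a deterministic function of the tilt strength.
    rng_comp = np.random.default_rng(children[_SS_COMPOSITIONS])
    base_comp = rng_comp.dirichlet(np.full(20, 700.0), size=spec.n_tfs)
    rng_seq = np.random.default_rng(children[_SS_SEQUENCES])
    lo, hi = spec.sequence_length_range
    lengths = rng_seq.integers(lo, hi + 1, size=spec.n_tfs)
    uniforms = [rng_seq.random(int(L)) for L in lengths]

    tilted = np.zeros(spec.n_tfs, dtype=bool)
    tilted[:n_a] = True
    # Per-protein tilt: random positive weights over the per-property
    # directions, so each planted feature carries partly independent signal.
    if spec.effect_size > 0:
        G = _signal_directions(table, informative)
        weights_ip = rng_comp.uniform(0.8, 1.2, size=(n_a, G.shape[0]))
        tilt_dir = weights_ip @ G  # (n_a, 20), entries sum to zero per row
    else:
        tilt_dir = np.zeros((n_a, 20))

    id_index = {pid: i for i, pid in enumerate(ids)}
    inf0 = [p - 1 for p in informative]
    V_inf = table.value_matrix()[inf0]  # (n_inf, 20)
    all_pairs = positives + [p for cls in ("absolute", "partial", "ppi")
                             for p in neg_pairs[cls]]
    pos_mask = np.zeros(len(all_pairs), dtype=bool)
    pos_mask[:len(positives)] = True

    # The tilt is additive — q' = q + lam_i * tilt_dir_i — with every
    # direction orthogonal to the composition simplex and invisible to the
    # non-informative scales, so each tilted protein's expected shift is
    # exactly invisible to the non-informative features, whatever its
    # baseline composition.  Positivity binds per protein: each protein is
    # tilted by the requested strength or by 98% of its own positivity
    # bound, whichever is smaller, so a single extreme baseline does not
    # cap the whole pool.
    if spec.effect_size > 0:
        base_a = base_comp[:n_a]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(tilt_dir < 0,
                              (base_a - 1e-4) / np.abs(tilt_dir), np.inf)
        lam_bound = 0.98 * ratios.min(axis=1)  # per-protein cap
        lam_max = float(np.quantile(lam_bound, 0.9))
    else:
        lam_bound = np.zeros(n_a)
        lam_max = 0.0

    def compositions(lam: float) -> np.ndarray:
        comp = base_comp.copy()
        comp[:n_a] = base_comp[:n_a] + \
            np.minimum(lam, lam_bound)[:, None] * tilt_dir
        return comp

    _alphabet_bytes = np.frombuffer(_ALPHABET22.encode("ascii"),
                                    dtype=np.uint8)
    _code_of = np.full(128, -1, dtype=np.int8)
    for _j, _aa in enumerate(STANDARD_AA):
        _code_of[ord(_aa)] = _j

    def _cumulative(comp: np.ndarray) -> np.ndarray:
        scale = 1.0 - spec.x_rate - spec.u_rate
        probs = np.column_stack([comp * scale,
                                 np.full(len(comp), spec.x_rate),
                                 np.full(len(comp), spec.u_rate)])
        cum = np.cumsum(probs, axis=1)
        cum[:, -1] = 1.0
        return cum

    def make_sequences(lam: float) -> list[str]:
        """Sequences with the tilt confined to the mid section.

        The planted signal emulates a central interaction domain: terminal
        sections always follow the baseline composition, the middle 60%
        follows the (possibly tilted) composition.
        """
        cum_base = _cumulative(base_comp)
        cum_tilt = _cumulative(compositions(lam))
        seqs = []
        for i in range(spec.n_tfs):
            u = uniforms[i]
            t = len(u) // 5
            codes = np.searchsorted(cum_base[i], u, side="right")
            codes[t:len(u) - t] = np.searchsorted(cum_tilt[i],
                                                  u[t:len(u) - t],
                                                  side="right")
            seqs.append(_alphabet_bytes[codes].tobytes().decode("ascii"))
        return seqs

    def standardized_shifts(seqs: list[str]) -> np.ndarray:
        """Class shift of the pair-level informative property means.

        The planted effect is defined on the pair-level mean of each
        informative property over the planted (mid) section — the
        mid-segment property mean averaged over the two members —
        standardized by the pooled deviation of the pure classes:
        positives and absolute negatives.  Partial negatives are a
        mixture whose spread is signal, not noise.
        """
        tf_means = np.zeros((spec.n_tfs, len(inf0)))
        for i, s in enumerate(seqs):
            codes = _code_of[np.frombuffer(s.encode("ascii"),
                                           dtype=np.uint8)]
            t = len(codes) // 5
            codes = codes[t:len(codes) - t]
            codes = codes[codes >= 0]
            comp = np.bincount(codes, minlength=20) / max(len(codes), 1)
            tf_means[i] = V_inf @ comp
        stat = np.array(
            [(tf_means[id_index[a]] + tf_means[id_index[b]]) / 2.0
             for a, b in all_pairs])
        pos, neg = stat[pos_mask], stat[~pos_mask]
        pure_neg = stat[len(positives):
                        len(positives) + spec.n_negative_per_class]
        n1, n2 = len(pos), len(pure_neg)
        pooled_var = (((n1 - 1) * pos.var(axis=0, ddof=1)
                       + (n2 - 1) * pure_neg.var(axis=0, ddof=1))
                      / (n1 + n2 - 2))
        return (pos.mean(axis=0) - neg.mean(axis=0)) / np.sqrt(pooled_var)

    lam = 0.0
    if spec.effect_size > 0:
        target = spec.effect_size

        def achieved(l: float) -> float:
            # Calibrate the weakest informative property, so every planted
            # feature carries at least the requested effect.
            return float(np.min(standardized_shifts(make_sequences(l))))

        reachable = achieved(lam_max)
        if reachable < target:
            raise FeasibilityError(
                f"effect_size={target} is unreachable with valid "
                f"compositions (at most {reachable:.2f} sd at the "
                f"positivity-bounded tilt {lam_max:.4f}); use a smaller "
                "effect_size")
        lam_lo, lam_hi = 0.0, lam_max
        for _ in range(40):
            mid = 0.5 * (lam_lo + lam_hi)
            if achieved(mid) < target:
                lam_lo = mid
            else:
                lam_hi = mid
        lam = lam_hi

    seq_strings = make_sequences(lam)
    sequences = {pid: ProteinRecord(pid, s)
                 for pid, s in zip(ids, seq_strings)}

    def record(a: str, b: str, label: str, neg_class: str | None,
               mi_type: str | None) -> InteractionRecord:
        from .features import canonical_pair
        first, second = canonical_pair(sequences[a], sequences[b])
        return InteractionRecord(first.id, second.id, label,
                                 neg_class=neg_class, mi_type=mi_type)

    records = [record(a, b, "positive", None, "MI:0407")
               for a, b in positives]
    for cls in ("absolute", "partial", "ppi"):
        records.extend(record(a, b, "negative", cls, None)
                       for a, b in neg_pairs[cls])
    interactions = InteractionSet(records, universe=set(ids))
    _dataset.validate_interaction_set(interactions, known_partners)

    measured = (standardized_shifts(seq_strings)
                if spec.effect_size > 0 else np.zeros(len(inf0)))
    # The tilt lives in the mid section only, so the signal-bearing
    # features are the two members' mid-segment means per informative
    # property; terminal-segment features of those properties stay null.
    planted = []
    for p0 in inf0:
        for member in (1, 2):
            planted.append(compose_feature(
                FeatureTriple(member, "M", p0), spec.n_properties))
    # One designated feature per informative property, alternating between
    # the two member slots so the set spans both pair members (a classifier
    # needs both to resolve partial negatives, whose single tilted member
    # mimics a true pair on one side).
    primary = [compose_feature(FeatureTriple(1 + (row % 2), "M", p0),
                               spec.n_properties)
               for row, p0 in enumerate(inf0)]
    decoys = [j for j in range(6 * spec.n_properties) if j not in set(planted)]
    ground_truth = {
        "spec": dataclasses.asdict(spec),
        "informative_properties": list(informative),
        "informative_accessions": [table.accessions[p] for p in inf0],
        "tilt_strength": lam,
        "measured_standardized_shift": measured.tolist(),
        "planted_feature_indices": planted,
        "primary_planted_indices": primary,
        "decoy_feature_indices": decoys,
        "pools": {"interaction_prone": pool_a, "promiscuous": pool_b,
                  "isolated": pool_c},
    }
    aaindex_text = write_aaindex1(table)
    # Round-trip guard: the emitted text must reproduce the table exactly.
    assert filter_complete(parse_aaindex1(aaindex_text)).value_matrix().shape \
        == table.value_matrix().shape
    return SyntheticStudy(spec=spec, table=table, sequences=sequences,
                          interactions=interactions,
                          known_partners=known_partners,
                          ground_truth=ground_truth,
                          aaindex_text=aaindex_text)


def default_candidate_pool(study: SyntheticStudy, n_candidates: int = 50
                           ) -> list[int]:
    """The standard desk-scale wrapper pool: the primary planted feature of
    every informative property plus the first non-informative decoys, up to
    ``n_candidates`` columns in ascending index order."""
    primary = study.ground_truth["primary_planted_indices"]
    decoys = study.ground_truth["decoy_feature_indices"]
    need = n_candidates - len(primary)
    if need < 0 or need > len(decoys):
        raise ValueError(f"cannot build a pool of {n_candidates} features")
    return sorted(primary + decoys[:need])
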