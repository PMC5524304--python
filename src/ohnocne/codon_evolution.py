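"""Branch-partitioned codon substitution models (Goldman-Yang form) with ML fitting.

The model assigns every branch of a rooted, tagged tree to an ω class and
shares a single transition/transversion ratio κ and codon equilibrium
frequencies π across the tree:

* model A — one ω for every branch;
* model B — ω^p for post-duplication paralog branches (classes ``a`` and ``b``
  jointly, or branches tagged ``p``), ω^r for the remaining branches;
* model C — separate ω^a and ω^b for the two paralog clades, ω^r elsewhere.

Instantaneous rates between codons differing at one nucleotide are
proportional to π_target, multiplied by κ for transitions and by the branch's
ω for nonsynonymous changes; multi-nucleotide changes are forbidden. The
matrix is scaled to one expected substitution per codon per unit branch
length. Likelihoods use Felsenstein pruning over the 61 sense codons of the
universal code, with per-node rescaling; transition matrices come from the
eigendecomposition of the reversible rate matrix in its symmetrised form.

Nested models are compared with likelihood-ratio tests: 2ΔlnL against χ² with
df equal to the difference in ω-class counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy import optimize, stats

from .errors import FitError, ValidationError
from .io_formats import LabeledTree, read_labeled_tree

# ---------------------------------------------------------------------------
# Genetic code tables (universal code, 61 sense codons)

_TABLE = unambiguous_dna_by_id[1]
CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product("TCAG", repeat=3))
    if c not in _TABLE.stop_codons
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO_ACID = tuple(_TABLE.forward_table[c] for c in CODONS)
N_CODONS = len(CODONS)  # 61

_PURINES = {"A", "G"}


def _pair_tables():
    ii, jj, ts, nonsyn = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            a, b = diffs[0]
            ii.append(i)
            jj.append(j)
            ts.append((a in _PURINES) == (b in _PURINES))
            nonsyn.append(AMINO_ACID[i] != AMINO_ACID[j])
    return (np.array(ii), np.array(jj), np.array(ts, bool), np.array(nonsyn, bool))

_PAIR_I, _PAIR_J, _IS_TS, _IS_NONSYN = _pair_tables()


# ---------------------------------------------------------------------------
# Data containers


@dataclass
class CodonAlignment:
    """Gap-free, in-frame codon alignment over the 61 sense codons."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self):
        if not self.sequences or len(self.taxa) != len(self.sequences):
            raise ValidationError("taxa and sequences must align and be non-empty")
        lens = {len(s) for s in self.sequences}
        if len(lens) != 1 or next(iter(lens)) % 3 != 0 or next(iter(lens)) == 0:
            raise ValidationError("sequences must share one positive length divisible by 3")
        self.sequences = [s.upper() for s in self.sequences]
        for t, s in zip(self.taxa, self.sequences):
            for k in range(0, len(s), 3):
                if s[k : k + 3] not in CODON_INDEX:
                    raise ValidationError(
                        f"{t}: codon {s[k:k + 3]!r} at position {k} is a stop/ambiguous codon"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codon_matrix(self) -> np.ndarray:
        """(n_taxa, n_codons) matrix of codon indices."""
        return np.array(
            [
                [CODON_INDEX[s[k : k + 3]] for k in range(0, len(s), 3)]
                for s in self.sequences
            ],
            dtype=np.int64,
        )

    def f3x4_frequencies(self) -> np.ndarray:
        """Empirical codon frequencies from positional nucleotide frequencies."""
        counts = np.zeros((3, 4))
        key = {b: k for k, b in enumerate("TCAG")}
        for s in self.sequences:
            for k, base in enumerate(s):
                counts[k % 3, key[base]] += 1
        posfreq = counts / counts.sum(axis=1, keepdims=True)
        pi = np.array(
            [posfreq[0, key[c[0]]] * posfreq[1, key[c[1]]] * posfreq[2, key[c[2]]]
             for c in CODONS]
        )
        pi = np.clip(pi, 1e-10, None)
        return pi / pi.sum()

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        from Bio import SeqIO

        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in recs], [str(r.seq) for r in recs])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, s in zip(self.taxa, self.sequences):
                fh.write(f">{t}\n{s}\n")


@dataclass
class ModelSpec:
    """Which ω classes exist and how branch tags map onto them."""

    model: str  # 'A', 'B' or 'C'
    codon_frequencies: str = "F3x4"  # or 'equal'

    def __post_init__(self):
        if self.model not in ("A", "B", "C"):
            raise ValidationError("model must be 'A', 'B' or 'C'")
        if self.codon_frequencies not in ("F3x4", "equal"):
            raise ValidationError("codon_frequencies must be 'F3x4' or 'equal'")

    @property
    def n_omega(self) -> int:
        return {"A": 1, "B": 2, "C": 3}[self.model]

    @property
    def omega_names(self) -> tuple[str, ...]:
        return {"A": ("omega",), "B": ("omega_r", "omega_p"),
                "C": ("omega_r", "omega_a", "omega_b")}[self.model]

    def class_index(self, tag: str) -> int:
        if self.model == "A":
            return 0
        if self.model == "B":
            return 0 if tag == "r" else 1
        if tag == "r":
            return 0
        if tag == "a":
            return 1
        if tag == "b":
            return 2
        raise ValidationError(
            f"branch tag {tag!r} is ambiguous under model C (use 'a'/'b'/'r')"
        )


@dataclass
class CodonModelFit:
    spec: ModelSpec
    tree: LabeledTree
    lnL: float
    kappa: float
    omegas: dict[str, float]
    branch_lengths: dict[int, float]
    free_parameter_count: int
    converged: bool
    boundary_flags: list[str] = field(default_factory=list)
    frequencies: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "model": self.spec.model,
            "lnL": self.lnL,
            "kappa": self.kappa,
            **self.omegas,
            "free_parameters": self.free_parameter_count,
            "converged": self.converged,
            "boundary_flags": self.boundary_flags,
        }


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities

OMEGA_BOUNDS = (1e-6, 50.0)
KAPPA_BOUNDS = (1e-3, 200.0)
BL_BOUNDS = (1e-9, 25.0)


def build_rate_matrix(kappa: float, omega: float, codon_frequencies: np.ndarray) -> np.ndarray:
    """Scaled 61x61 Goldman-Yang rate matrix (1 expected substitution per unit time)."""
    pi = np.asarray(codon_frequencies, float)
    if pi.shape != (N_CODONS,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValidationError("codon_frequencies must be 61 non-negative values summing to 1")
    if kappa <= 0 or omega < 0:
        raise ValidationError("need kappa > 0 and omega >= 0")
    Q = np.zeros((N_CODONS, N_CODONS))
    rates = pi[_PAIR_J] * np.where(_IS_TS, kappa, 1.0) * np.where(_IS_NONSYN, omega, 1.0)
    Q[_PAIR_I, _PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    if scale <= 0:
        raise ValidationError("degenerate rate matrix (zero total rate)")
    return Q / scale


def _eigen(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a reversible Q via its symmetrised form."""
    sq = np.sqrt(pi)
    B = Q * (sq[:, None] / sq[None, :])
    B = (B + B.T) / 2  # symmetrise away fp noise
    w, U = np.linalg.eigh(B)
    left = U / sq[:, None]
    right = U.T * sq[None, :]
    return w, left, right


def _transition_matrix(w, left, right, t: float) -> np.ndarray:
    P = (left * np.exp(w * t)) @ right
    np.clip(P, 0.0, None, out=P)
    return P


# ---------------------------------------------------------------------------
# Tree indexing


class _TreeIndex:
    """Flat postorder view of a LabeledTree for pruning and simulation."""

    def __init__(self, lt: LabeledTree, taxa: list[str], spec: ModelSpec):
        nodes = list(lt.tree.postorder_node_iter())
        self.nodes = nodes
        self.node_id = {id(nd): k for k, nd in enumerate(nodes)}
        self.root_id = self.node_id[id(lt.tree.seed_node)]
        self.parent = np.full(len(nodes), -1)
        self.lengths = np.zeros(len(nodes))
        self.omega_class = np.zeros(len(nodes), np.int64)
        self.leaf_taxon = np.full(len(nodes), -1)
        self.children: list[list[int]] = [[] for _ in nodes]
        taxon_pos = {t: i for i, t in enumerate(taxa)}
        leaf_names = set()
        for k, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self.node_id[id(nd.parent_node)]
                self.parent[k] = p
                self.children[p].append(k)
                self.lengths[k] = nd.edge.length if nd.edge.length is not None else 0.0
                self.omega_class[k] = spec.class_index(nd.omega_class)
            if nd.is_leaf():
                name = nd.taxon.label
                leaf_names.add(name)
                if name not in taxon_pos:
                    raise ValidationError(f"tree leaf {name!r} missing from alignment")
                self.leaf_taxon[k] = taxon_pos[name]
        if leaf_names != set(taxa):
            raise ValidationError(
                f"alignment taxa {sorted(set(taxa) - leaf_names)} missing from tree"
            )
        # Root-edge collapse: a bifurcating root's two branches form a single
        # edge of the unrooted tree (only their combined length is meaningful
        # for a reversible model), so they are merged onto one branch that must
        # carry a single ω class. Leaving them separate with different classes
        # would hand the richer model a spuriously identifiable extra
        # dimension and distort likelihood-ratio tests.
        self.fixed_zero: set[int] = set()
        rc = self.children[self.root_id]
        if len(rc) == 2:
            c0, c1 = rc
            cls0, cls1 = int(self.omega_class[c0]), int(self.omega_class[c1])
            if cls0 != cls1:
                bg = spec.class_index("r")
                if bg not in (cls0, cls1):
                    raise ValidationError(
                        "the two root branches carry different non-background "
                        "ω classes; re-root the tree (e.g. trifurcating root) "
                        "so each unrooted edge has one class"
                    )
                keep = cls0 if cls0 != bg else cls1
                self.omega_class[c0] = keep
            self.lengths[c0] += self.lengths[c1]
            self.lengths[c1] = 0.0
            self.fixed_zero.add(c1)
        self.edge_ids = [k for k in range(len(nodes))
                         if k != self.root_id and k not in self.fixed_zero]

    @property
    def n_free_lengths(self) -> int:
        return len(self.edge_ids)


# ---------------------------------------------------------------------------
# Likelihood


def _compress_sites(codon_mat: np.ndarray):
    patterns, inverse, counts = np.unique(
        codon_mat.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts  # (n_taxa, n_patterns), weights


def _class_decomps(tindex: _TreeIndex, pi, kappa, omegas):
    decomp = {}
    for k in range(len(tindex.nodes)):
        if k == tindex.root_id:
            continue
        cls = int(tindex.omega_class[k])
        if cls not in decomp:
            Q = build_rate_matrix(kappa, omegas[cls], pi)
            decomp[cls] = _eigen(Q, pi)
    return decomp


def _pruned_loglik(tindex: _TreeIndex, patterns, weights, pi, kappa, omegas, lengths,
                   decomp=None):
    if decomp is None:
        decomp = _class_decomps(tindex, pi, kappa, omegas)
    npat = patterns.shape[1]
    partial = [None] * len(tindex.nodes)
    logscale = np.zeros(npat)
    for k, nd in enumerate(tindex.nodes):
        if tindex.leaf_taxon[k] >= 0:
            continue
        L = np.ones((N_CODONS, npat))
        for c in tindex.children[k]:
            w, left, right = decomp[int(tindex.omega_class[c])]
            P = _transition_matrix(w, left, right, lengths[c])
            if tindex.leaf_taxon[c] >= 0:
                Lc = P[:, patterns[tindex.leaf_taxon[c]]]
            else:
                Lc = P @ partial[c]
            L *= Lc
        if k != tindex.root_id:
            mx = L.max(axis=0)
            mx[mx == 0] = 1.0
            L /= mx
            logscale += np.log(mx)
        partial[k] = L
    site = pi @ partial[tindex.root_id]
    if np.any(site <= 0) or not np.all(np.isfinite(site)):
        raise FitError("non-finite site likelihood (underflow or invalid parameters)")
    return float(np.dot(weights, np.log(site) + logscale))


def log_likelihood(
    alignment: CodonAlignment,
    tree: LabeledTree | str,
    spec: ModelSpec,
    *,
    kappa: float,
    omegas: dict[str, float] | list[float] | float,
    branch_lengths: dict | None = None,
    frequencies: np.ndarray | None = None,
) -> float:
    """lnL of the alignment under the branch-partitioned model.

    ``omegas`` maps the spec's omega names (or a list in name order, or a
    scalar for model A) to values. Branch lengths default to those on the tree.
    """
    lt = read_labeled_tree(tree) if isinstance(tree, str) else tree
    tindex = _TreeIndex(lt, alignment.taxa, spec)
    om = _omega_vector(spec, omegas)
    pi = _frequencies(spec, alignment, frequencies)
    patterns, weights = _compress_sites(alignment.codon_matrix())
    lengths = tindex.lengths.copy()
    if branch_lengths:
        for k, v in branch_lengths.items():
            lengths[k] = v
    return _pruned_loglik(tindex, patterns, weights, pi, kappa, om, lengths)


def _omega_vector(spec: ModelSpec, omegas) -> np.ndarray:
    if np.isscalar(omegas):
        omegas = [omegas]
    if isinstance(omegas, dict):
        return np.array([omegas[name] for name in spec.omega_names], float)
    arr = np.asarray(omegas, float)
    if arr.size != spec.n_omega:
        raise ValidationError(f"model {spec.model} needs {spec.n_omega} omega values")
    return arr


def _frequencies(spec: ModelSpec, alignment: CodonAlignment, override=None) -> np.ndarray:
    if override is not None:
        pi = np.asarray(override, float)
        return pi / pi.sum()
    if spec.codon_frequencies == "equal":
        return np.full(N_CODONS, 1.0 / N_CODONS)
    return alignment.f3x4_frequencies()


# ---------------------------------------------------------------------------
# Fitting


def fit(
    alignment: CodonAlignment,
    tree: LabeledTree | str,
    spec: ModelSpec,
    *,
    init: dict | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    fix_branch_lengths: bool = False,
    maxiter: int = 2000,
) -> CodonModelFit:
    """Maximum-likelihood fit of κ, the ω classes and (by default) branch lengths.

    Optimisation is bounded quasi-Newton (L-BFGS-B) on log-transformed
    parameters, started from ``init`` (or mild defaults) plus ``n_restarts``
    jittered restarts with a fixed seed. ``init`` may carry 'kappa', 'omegas'
    (name->value) and 'branch_lengths'.
    """
    lt = read_labeled_tree(tree) if isinstance(tree, str) else tree
    lt = lt.clone()
    tindex = _TreeIndex(lt, alignment.taxa, spec)
    pi = _frequencies(spec, alignment)
    patterns, weights = _compress_sites(alignment.codon_matrix())
    nw = spec.n_omega

    init = init or {}
    kappa0 = float(init.get("kappa", 2.0))
    om0 = _omega_vector(spec, init["omegas"]) if "omegas" in init else np.full(nw, 0.3)
    bl0 = tindex.lengths[tindex.edge_ids]
    if "branch_lengths" in init:
        for k, v in init["branch_lengths"].items():
            if k in tindex.edge_ids:
                bl0[tindex.edge_ids.index(k)] = v
    bl0 = np.clip(bl0, 0.01, None)

    def unpack(x):
        kappa = np.exp(x[0])
        om = np.exp(x[1 : 1 + nw])
        lengths = tindex.lengths.copy()
        if not fix_branch_lengths:
            lengths[tindex.edge_ids] = np.exp(x[1 + nw :])
        return kappa, om, lengths

    # Rate-matrix decompositions depend only on (kappa, omegas); cache them so
    # the optimiser's branch-length finite differences reuse the spectra.
    cache: dict = {}

    def negll(x):
        kappa, om, lengths = unpack(x)
        key = (float(kappa), om.tobytes())
        decomp = cache.get(key)
        if decomp is None:
            if len(cache) > 16:
                cache.clear()
            decomp = cache[key] = _class_decomps(tindex, pi, kappa, om)
        try:
            return -_pruned_loglik(
                tindex, patterns, weights, pi, kappa, om, lengths, decomp=decomp
            )
        except FitError:
            return 1e12

    lo = [np.log(KAPPA_BOUNDS[0])] + [np.log(OMEGA_BOUNDS[0])] * nw
    hi = [np.log(KAPPA_BOUNDS[1])] + [np.log(OMEGA_BOUNDS[1])] * nw
    if not fix_branch_lengths:
        lo += [np.log(BL_BOUNDS[0])] * tindex.n_free_lengths
        hi += [np.log(BL_BOUNDS[1])] * tindex.n_free_lengths
    bounds = list(zip(lo, hi))

    x0_base = np.concatenate(
        [[np.log(kappa0)], np.log(om0)] + ([np.log(bl0)] if not fix_branch_lengths else [])
    )
    rng = np.random.default_rng(seed)
    starts = [x0_base]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(np.clip(x0_base + rng.normal(0, 0.5, x0_base.size), lo, hi))

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 5e-10, "gtol": 1e-6},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    kappa, om, lengths = unpack(best.x)
    flags = []
    for name, val in zip(spec.omega_names, om):
        if val <= OMEGA_BOUNDS[0] * 1.01:
            flags.append(f"{name} at lower bound")
        elif val >= OMEGA_BOUNDS[1] * 0.99:
            flags.append(f"{name} at upper bound")
    for k, nd in enumerate(tindex.nodes):
        if nd.parent_node is not None:
            nd.edge.length = float(lengths[k])
    n_free = 1 + nw + (0 if fix_branch_lengths else tindex.n_free_lengths)
    fit_ = CodonModelFit(
        spec=spec,
        tree=lt,
        lnL=-float(best.fun),
        kappa=float(kappa),
        omegas=dict(zip(spec.omega_names, map(float, om))),
        branch_lengths={k: float(lengths[k]) for k in tindex.edge_ids},
        free_parameter_count=n_free,
        converged=any_converged,
        boundary_flags=flags,
        frequencies=pi,
    )
    if not any_converged and best.fun >= 1e11:
        raise FitError("optimisation failed from every start", best_fit=fit_)
    return fit_


def lrt(fit_null: CodonModelFit, fit_alt: CodonModelFit) -> LRTResult:
    """Likelihood-ratio test of nested branch models (A in B in C)."""
    order = {"A": 0, "B": 1, "C": 2}
    if order[fit_null.spec.model] >= order[fit_alt.spec.model]:
        raise ValidationError(
            f"model {fit_null.spec.model} is not nested in {fit_alt.spec.model}"
        )
    stat = max(0.0, 2.0 * (fit_alt.lnL - fit_null.lnL))
    df = fit_alt.spec.n_omega - fit_null.spec.n_omega
    return LRTResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# Simulation


def simulate(
    tree: LabeledTree | str,
    spec: ModelSpec,
    *,
    kappa: float,
    omegas,
    n_codons: int,
    seed: int,
    frequencies: np.ndarray | None = None,
) -> CodonAlignment:
    """Simulate a codon alignment along the tagged tree (root draw from π)."""
    if n_codons < 1:
        raise ValidationError("n_codons must be >= 1")
    lt = read_labeled_tree(tree) if isinstance(tree, str) else tree
    leaf_names = lt.leaf_names
    tindex = _TreeIndex(lt, leaf_names, spec)
    om = _omega_vector(spec, omegas)
    if frequencies is None:
        pi = np.full(N_CODONS, 1.0 / N_CODONS)
    else:
        pi = np.asarray(frequencies, float)
        pi = pi / pi.sum()
    rng = np.random.default_rng(seed)
    cum = {}
    for cls in set(int(c) for k, c in enumerate(tindex.omega_class) if k != tindex.root_id):
        Q = build_rate_matrix(kappa, om[cls], pi)
        cum[cls] = None, Q
    states = {tindex.root_id: rng.choice(N_CODONS, size=n_codons, p=pi)}
    preorder = list(reversed(range(len(tindex.nodes))))  # postorder reversed
    eig = {cls: _eigen(Q, pi) for cls, (_, Q) in cum.items()}
    for k in preorder:
        p = tindex.parent[k]
        if p < 0:
            continue
        w, left, right = eig[int(tindex.omega_class[k])]
        P = _transition_matrix(w, left, right, tindex.lengths[k])
        P = P / P.sum(axis=1, keepdims=True)
        cumP = np.cumsum(P, axis=1)
        parent_states = states[p]
        child = np.empty(n_codons, np.int64)
        u = rng.random(n_codons)
        for s in np.unique(parent_states):
            idx = np.nonzero(parent_states == s)[0]
            child[idx] = np.searchsorted(cumP[s], u[idx], side="right")
        np.clip(child, 0, N_CODONS - 1, out=child)
        states[k] = child
    seqs = {}
    for k in range(len(tindex.nodes)):
        ti = tindex.leaf_taxon[k]
        if ti >= 0:
            seqs[leaf_names[ti]] = "".join(CODONS[c] for c in states[k])
    return CodonAlignment(taxa=leaf_names, sequences=[seqs[t] for t in leaf_names])
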