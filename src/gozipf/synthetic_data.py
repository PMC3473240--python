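"""Synthetic GAF corpora and toy ontologies with known statistics.

Real GOA releases are large external downloads; every stage of the
pipeline is instead exercised on generated corpora whose ground truth is
known exactly. Term frequencies — not ranks — are drawn from the
discrete power law P(f) ~ f^-beta, which is precisely the Pareto-of-
frequencies form the fitter assumes; annotation tokens are then sampled
proportional to those target frequencies, and evidence codes i.i.d.
from a configurable profile. A toy is_a tree provides terms of known
depth so that the coupling between term frequency and ontology depth
("frequent terms are generic, hence shallow") can be switched on.

Synthetic GO ids use the reserved GO:9xxxxxx range, which does not
collide with real GO identifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import zeta

from gozipf.ontology_io import ASPECT_TO_NAMESPACE, AnnotationRecord

_NAMESPACE_TO_OBO = {
    "MF": "molecular_function",
    "BP": "biological_process",
    "CC": "cellular_component",
}
_NAMESPACE_TO_ASPECT = {v: k for k, v in ASPECT_TO_NAMESPACE.items()}

#: Rough evidence-code mix of a mixed manual/electronic annotation
#: release: slightly over half electronic (IEA), a third experimental
#: codes, the rest sequence-similarity (ISS, neither HC nor LC).
DEFAULT_EVIDENCE_PROFILE = {
    "IEA": 0.55,
    "IDA": 0.14,
    "IMP": 0.08,
    "TAS": 0.07,
    "IPI": 0.05,
    "ISS": 0.11,
}


class DiscretePowerLawSampler:
    """Inverse-CDF sampler for P(X = x) = x^-beta / zeta(beta, xmin).

    The CDF is tabulated up to ``cap``; the rare draws falling beyond
    the table are inverted exactly against the analytic Hurwitz-zeta
    CCDF by exponential search, so no probability mass is distorted.
    """

    def __init__(self, beta: float, xmin: int = 1, cap: int = 10**6):
        if beta <= 1:
            raise ValueError(f"beta must exceed 1, got {beta}")
        if xmin < 1:
            raise ValueError(f"xmin must be a positive integer, got {xmin}")
        self.beta = float(beta)
        self.xmin = int(xmin)
        self.cap = max(int(cap), self.xmin + 1)
        self._norm = zeta(self.beta, self.xmin)
        xs = np.arange(self.xmin, self.cap + 1, dtype=np.float64)
        self._cdf = np.cumsum(xs**-self.beta) / self._norm

    def _ccdf(self, x: float) -> float:
        """P(X >= x), exact."""
        return zeta(self.beta, x) / self._norm

    def _invert_tail(self, u: float) -> int:
        # smallest x with P(X <= x) >= u, for u beyond the table
        lo = self.cap
        hi = 2 * self.cap
        while 1.0 - self._ccdf(hi + 1) < u:
            lo, hi = hi, 2 * hi
        while lo < hi:
            mid = (lo + hi) // 2
            if 1.0 - self._ccdf(mid + 1) >= u:
                hi = mid
            else:
                lo = mid + 1
        return lo

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 0:
            raise ValueError("n must be non-negative")
        u = rng.random(n)
        idx = np.searchsorted(self._cdf, u, side="left")
        out = idx + self.xmin
        over = idx >= self._cdf.size
        for i in np.nonzero(over)[0]:
            out[i] = self._invert_tail(u[i])
        return out.astype(np.int64)


def sample_discrete_power_law(
    beta: float, xmin: int, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """n i.i.d. draws from the discrete power law at (beta, xmin).

    Deterministic for a given integer seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return DiscretePowerLawSampler(beta, xmin).sample(n, rng)


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for a synthetic annotation corpus.

    Defaults emulate one sub-ontology of a mid-sized genome annotation
    release: ~50k annotation lines over ~2.5k distinct terms, a
    frequency exponent of 2 (the value typical of natural-language
    corpora and of GO annotation alike), and a mixed manual/electronic
    evidence profile.
    """

    n_annotations: int = 50_000
    n_terms: int = 2_500
    beta_true: float = 2.0
    xmin: int = 1
    aspect: str = "P"
    evidence_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVIDENCE_PROFILE)
    )
    shallow_frequent_coupling: bool = False
    seed: int = 0
    source_label: str = "synthetic"
    id_offset: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 4:
            raise ValueError("n_terms must be at least 4")
        if self.beta_true <= 1:
            raise ValueError("beta_true must exceed 1")
        if self.xmin < 1:
            raise ValueError("xmin must be a positive integer")
        total = sum(self.evidence_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"evidence profile must sum to 1, sums to {total}")
        if self.aspect not in ASPECT_TO_NAMESPACE and (
            self.aspect not in ASPECT_TO_NAMESPACE.values()
        ):
            raise ValueError(f"unknown aspect {self.aspect!r}")

    @property
    def aspect_letter(self) -> str:
        if self.aspect in ASPECT_TO_NAMESPACE:
            return self.aspect
        return _NAMESPACE_TO_ASPECT[_NAMESPACE_TO_OBO[self.aspect]]

    @property
    def namespace(self) -> str:
        return ASPECT_TO_NAMESPACE[self.aspect_letter]


@dataclass
class GroundTruth:
    """Generator bookkeeping for one synthetic corpus."""

    beta_true: float
    xmin: int
    terms: list[str]
    target_frequencies: np.ndarray
    evidence_profile: dict[str, float]
    depths: dict[str, int] | None = None
    obo_text: str | None = None


def _synthetic_id(i: int) -> str:
    if i >= 900_000:
        raise ValueError("synthetic id space (GO:9xxxxxx) exhausted")
    return f"GO:9{i:06d}"


def generate_toy_obo(
    n_levels: int,
    branching: int,
    seed: int = 0,
    namespaces: tuple[str, ...] = ("MF", "BP", "CC"),
    n_cross_edges: int = 0,
    id_offset: int = 0,
) -> tuple[str, dict[str, int]]:
    """A balanced is_a tree per namespace, as OBO 1.2 text.

    Level 0 is the namespace root; each term at level d < n_levels-1 has
    ``branching`` children. Optional cross-edges add a second is_a
    parent one level up (chosen at random per seed), which keeps the
    graph a DAG and leaves every term's shortest-path depth unchanged.

    Returns the OBO text and the ground-truth map term -> depth.
    """
    if n_levels < 1 or branching < 1:
        raise ValueError("n_levels and branching must be at least 1")
    rng = np.random.default_rng(seed)
    lines = ["format-version: 1.2", "ontology: gozipf-toy", ""]
    depths: dict[str, int] = {}
    counter = id_offset
    for ns in namespaces:
        obo_ns = _NAMESPACE_TO_OBO[ns]
        levels: list[list[str]] = []
        for depth in range(n_levels):
            n_at_level = branching**depth
            ids = [_synthetic_id(counter + i) for i in range(n_at_level)]
            counter += n_at_level
            levels.append(ids)
            for j, term in enumerate(ids):
                depths[term] = depth
                stanza = [
                    "[Term]",
                    f"id: {term}",
                    f"name: toy {obo_ns} term depth {depth}",
                    f"namespace: {obo_ns}",
                ]
                if depth > 0:
                    parent = levels[depth - 1][j // branching]
                    stanza.append(f"is_a: {parent}")
                    if n_cross_edges > 0 and len(levels[depth - 1]) > 1:
                        if rng.random() < 0.5:
                            others = [p for p in levels[depth - 1] if p != parent]
                            extra = others[rng.integers(len(others))]
                            stanza.append(f"is_a: {extra}")
                lines.extend(stanza)
                lines.append("")
    return "\n".join(lines), depths


def generate_corpus(spec: CorpusSpec) -> tuple[list[AnnotationRecord], GroundTruth]:
    """Generate a synthetic GAF corpus with a power-law term-frequency tail.

    Target frequencies for the ``n_terms`` synthetic terms are drawn
    from the discrete power law at (beta_true, xmin); annotation records
    then sample terms with probability proportional to those targets, so
    the realised frequency table is a multinomial rendering of a
    power-law profile. With ``shallow_frequent_coupling`` the terms come
    from a toy ontology and the largest target frequencies are assigned
    to the shallowest terms, reproducing the generic-terms-are-frequent
    structure of real annotation.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_annotations < spec.n_terms:
        warnings.warn(
            "fewer annotations than terms: some terms will be unused",
            stacklevel=2,
        )
    freqs = sample_discrete_power_law(spec.beta_true, spec.xmin, spec.n_terms, rng)

    depths: dict[str, int] | None = None
    obo_text: str | None = None
    if spec.shallow_frequent_coupling:
        branching = 3
        n_levels = 1
        while (branching**n_levels - 1) // (branching - 1) < spec.n_terms + 1:
            n_levels += 1
        obo_text, full_depths = generate_toy_obo(
            n_levels, branching, seed=spec.seed, namespaces=(spec.namespace,),
            id_offset=spec.id_offset,
        )
        # skip the root; frequent terms go to shallow slots
        candidates = sorted(
            (t for t, d in full_depths.items() if d > 0),
            key=lambda t: (full_depths[t], t),
        )
        terms = candidates[: spec.n_terms]
        depths = {t: full_depths[t] for t in terms}
        # terms are sorted shallow-first: largest target -> shallowest term
        freqs = np.sort(freqs)[::-1]
    else:
        terms = [_synthetic_id(i + spec.id_offset) for i in range(spec.n_terms)]

    probs = freqs / freqs.sum()
    term_idx = rng.choice(spec.n_terms, size=spec.n_annotations, p=probs)
    codes = list(spec.evidence_profile)
    code_probs = np.array([spec.evidence_profile[c] for c in codes])
    code_idx = rng.choice(len(codes), size=spec.n_annotations, p=code_probs)
    n_objects = max(1, spec.n_terms // 2)
    obj_idx = rng.integers(n_objects, size=spec.n_annotations)

    aspect = spec.aspect_letter
    records = [
        AnnotationRecord(
            db="GOZIPF_SYN",
            db_object_id=f"OBJ{obj_idx[i]:06d}",
            go_id=terms[term_idx[i]],
            aspect=aspect,
            evidence_code=codes[code_idx[i]],
            taxon="taxon:0",
        )
        for i in range(spec.n_annotations)
    ]
    truth = GroundTruth(
        beta_true=spec.beta_true,
        xmin=spec.xmin,
        terms=list(terms),
        target_frequencies=np.asarray(freqs),
        evidence_profile=dict(spec.evidence_profile),
        depths=depths,
        obo_text=obo_text,
    )
    return records, truth
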