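"""End-to-end orchestration: corpora -> fits -> comparisons -> reports.

``run_pipeline`` takes a :class:`RunConfig` naming either real inputs (a
GAF file, optionally an OBO ontology) or synthetic corpus specs, builds
one corpus per (source, aspect, evidence-class) stratum, fits the
discrete power law to each term-frequency table, runs the depth and
exponent comparisons where the inputs allow, and optionally renders the
whole bundle to TSV/JSON files. Given the same config and seed the
outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gozipf import corpus_builder, depth_analysis, exponent_comparison, powerlaw
from gozipf.corpus_builder import Corpus, EmptyCorpusError, corpus_summary, \
    evidence_class, frequency_table
from gozipf.depth_analysis import DegenerateInputError, DepthComparison
from gozipf.exponent_comparison import ExponentRecord
from gozipf.ontology_io import ASPECT_TO_NAMESPACE, OntologyGraph, parse_gaf, \
    parse_obo
from gozipf.synthetic_data import CorpusSpec, generate_corpus

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


class ConfigurationError(ValueError):
    """The run configuration is inconsistent or incomplete."""


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of ``gaf`` or ``specs`` provides the annotations. The
    seed feeds every stochastic stage (corpus generation and bootstrap)
    and is recorded in every output artifact.
    """

    gaf: str | None = None
    obo: str | None = None
    specs: tuple[CorpusSpec, ...] = ()
    aspects: tuple[str, ...] = ("MF", "BP", "CC")
    evidence_classes: tuple[str, ...] = ("ALL",)
    n_bootstrap: int | None = 200
    min_tail: int = 10
    exclude_negated: bool = True
    require_depth: bool = False
    seed: int = 0
    out_dir: str | None = None
    source_label: str = ""


@dataclass
class ResultBundle:
    """Everything one pipeline run computed."""

    summary: pd.DataFrame
    fits: list[dict]
    exponent_records: list[ExponentRecord]
    depth_comparisons: list[DepthComparison]
    depth_test: dict | None
    comparison: dict
    ccdf_points: dict[str, np.ndarray]
    errors: list[str]
    config: RunConfig


def _normalise_aspect(aspect: str) -> str:
    return ASPECT_TO_NAMESPACE.get(aspect, aspect)


def _merge_graphs(graphs: list[OntologyGraph]) -> OntologyGraph:
    out = OntologyGraph()
    for g in graphs:
        out.graph.add_nodes_from(g.graph.nodes)
        out.graph.add_edges_from(g.graph.edges)
        out.names.update(g.names)
        out.namespace.update(g.namespace)
        out.alt_id.update(g.alt_id)
        out.obsolete.update(g.obsolete)
    return out


def _load_inputs(
    config: RunConfig,
) -> tuple[list[tuple[str, list]], OntologyGraph | None]:
    """Record groups (one per source) and an ontology graph, if any."""
    groups: list[tuple[str, list]] = []
    graphs: list[OntologyGraph] = []
    if config.gaf is not None and config.specs:
        raise ConfigurationError("give either a GAF file or synthetic specs, not both")
    if config.gaf is not None:
        with open(config.gaf) as fh:
            records = parse_gaf(fh)
        label = config.source_label or Path(config.gaf).stem
        groups.append((label, records))
    elif config.specs:
        for i, spec in enumerate(config.specs):
            if spec.id_offset == 0 and i > 0:
                spec = dataclasses.replace(spec, id_offset=10_000 * i)
            records, truth = generate_corpus(spec)
            groups.append((spec.source_label, records))
            if truth.obo_text is not None:
                graphs.append(parse_obo(truth.obo_text))
    else:
        raise ConfigurationError("no input: set gaf= or specs=")

    if config.obo is not None:
        with open(config.obo) as fh:
            graphs.append(parse_obo(fh))
    graph = _merge_graphs(graphs) if graphs else None
    if config.require_depth and graph is None:
        raise ConfigurationError(
            "depth analysis requested but no ontology (OBO) is available"
        )
    return groups, graph


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Run every analysis stage the configuration allows.

    Per-corpus failures (e.g. an empty post-filter stratum) are reported
    in ``errors`` and the run continues; configuration-level problems
    raise :class:`ConfigurationError`.
    """
    groups, graph = _load_inputs(config)
    aspects = tuple(_normalise_aspect(a) for a in config.aspects)
    classes = [evidence_class(name) for name in config.evidence_classes]

    corpora: list[Corpus] = []
    fits: list[dict] = []
    exp_records: list[ExponentRecord] = []
    depth_comparisons: list[DepthComparison] = []
    ccdf_points: dict[str, np.ndarray] = {}
    errors: list[str] = []

    corpus_index = 0
    for label, records in groups:
        for aspect in aspects:
            for ec in classes:
                key = f"{label}_{aspect}_{ec.name}"
                corpus_seed = (config.seed + 7919 * corpus_index) % _SEED_MOD
                corpus_index += 1
                try:
                    corpus = corpus_builder.build_corpus(
                        records, aspect, ec,
                        exclude_negated=config.exclude_negated,
                        graph=graph, source_label=label,
                    )
                except EmptyCorpusError as exc:
                    errors.append(f"{key}: {exc}")
                    continue
                corpora.append(corpus)
                table = frequency_table(corpus)
                freqs = table["frequency"].to_numpy()
                try:
                    fit = powerlaw.fit_power_law(
                        freqs, min_tail=config.min_tail,
                        n_bootstrap=config.n_bootstrap, seed=corpus_seed,
                    )
                except (powerlaw.NoCandidateError,
                        powerlaw.DegenerateTailError) as exc:
                    errors.append(f"{key}: {exc}")
                    continue
                curve = powerlaw.ccdf(freqs)
                ccdf_points[key] = np.column_stack([curve.x, curve.p])
                fits.append(
                    {
                        "source": label,
                        "aspect": aspect,
                        "evidence_class": ec.name,
                        "n": corpus.total_annotations,
                        "distinct": corpus.distinct_terms,
                        "xmin": fit.xmin,
                        "beta": fit.beta_hat,
                        "se": fit.se,
                        "ks": fit.ks_distance,
                        "n_tail": fit.n_tail,
                        "p_value": fit.p_value,
                        "plausible": fit.plausible,
                        "n_bootstrap": fit.n_bootstrap,
                        "seed": corpus_seed,
                    }
                )
                exp_records.append(
                    ExponentRecord(
                        source_label=label, aspect=aspect,
                        evidence_class=ec.name, beta=fit.beta_hat,
                        p_value=fit.p_value,
                        n_total=corpus.total_annotations,
                        n_distinct=corpus.distinct_terms,
                    )
                )
                if graph is not None:
                    try:
                        depth_comparisons.append(
                            depth_analysis.quartile_depth_comparison(
                                table, graph, corpus_label=key
                            )
                        )
                    except (KeyError, ValueError) as exc:
                        errors.append(f"{key}: depth skipped ({exc})")

    depth_test: dict | None = None
    if len(depth_comparisons) >= 2:
        try:
            t, df, p = depth_analysis.depth_significance(depth_comparisons)
            depth_test = {"t": t, "df": df, "p_two_sided": p}
        except DegenerateInputError as exc:
            errors.append(f"depth t-test skipped: {exc}")

    comparison = _compare(exp_records)
    bundle = ResultBundle(
        summary=corpus_summary(corpora),
        fits=fits,
        exponent_records=exp_records,
        depth_comparisons=depth_comparisons,
        depth_test=depth_test,
        comparison=comparison,
        ccdf_points=ccdf_points,
        errors=errors,
        config=config,
    )
    if config.out_dir is not None:
        render_tables(bundle, config.out_dir)
    return bundle


def _compare(records: list[ExponentRecord]) -> dict:
    comparison: dict = {"aspect_means": {}, "hc_lc": None, "size_association": None}
    base = [r for r in records if r.evidence_class == "ALL"] or records
    for aspect in ("MF", "BP", "CC"):
        if any(r.aspect == aspect for r in base):
            comparison["aspect_means"][aspect] = \
                exponent_comparison.group_mean_beta(base, aspect)
    by_cell: dict[tuple[str, str], dict[str, float]] = {}
    for r in records:
        by_cell.setdefault((r.source_label, r.aspect), {})[r.evidence_class] = r.beta
    pairs = [
        (v["HC"], v["LC"]) for v in by_cell.values() if "HC" in v and "LC" in v
    ]
    if len(pairs) >= 2:
        try:
            t, df, p2 = exponent_comparison.paired_t_test(pairs, sides="two")
            _, _, p1 = exponent_comparison.paired_t_test(pairs, sides="one")
            comparison["hc_lc"] = {
                "pairs": pairs, "t": t, "df": df,
                "p_two_sided": p2, "p_one_sided": p1,
            }
        except DegenerateInputError:
            pass
    if len(base) >= 3:
        corr_distinct, corr_total, _ = \
            exponent_comparison.size_exponent_association(base)
        comparison["size_association"] = {
            "spearman_beta_vs_distinct": corr_distinct,
            "spearman_beta_vs_total": corr_total,
        }
    return comparison


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def _config_hash(config: RunConfig) -> str:
    text = repr(dataclasses.asdict(config))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def render_tables(results: ResultBundle, out_dir: str) -> list[Path]:
    """Write the result bundle as TSV/JSON files; returns the paths written.

    Tabular output rounds beta and p-values to 2 decimals (the usual
    reporting precision); the JSON mirrors keep full precision.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = out / "summary.tsv"
    results.summary.to_csv(path, sep="\t", index=False)
    written.append(path)

    fit_rows = []
    for f in results.fits:
        fit_rows.append(
            {
                "source": f["source"], "aspect": f["aspect"],
                "evidence_class": f["evidence_class"],
                "n": f["n"], "distinct": f["distinct"], "xmin": f["xmin"],
                "beta": f"{f['beta']:.2f}",
                "p_value": "NA" if f["p_value"] is None else f"{f['p_value']:.2f}",
            }
        )
    path = out / "fits.tsv"
    pd.DataFrame(fit_rows).to_csv(path, sep="\t", index=False)
    written.append(path)
    path = out / "fits.json"
    _write_json(path, results.fits)
    written.append(path)

    if results.depth_comparisons:
        path = out / "depth.tsv"
        pd.DataFrame(
            [
                {
                    "corpus_label": c.corpus_label,
                    "n_top": c.n_top,
                    "mean_depth_top": c.mean_depth_top,
                    "n_bottom": c.n_bottom,
                    "mean_depth_bottom": c.mean_depth_bottom,
                }
                for c in results.depth_comparisons
            ]
        ).to_csv(path, sep="\t", index=False)
        written.append(path)

    comparison = dict(results.comparison)
    if results.depth_test is not None:
        comparison["depth_test"] = results.depth_test
    path = out / "comparison.json"
    _write_json(path, comparison)
    written.append(path)

    for key, points in results.ccdf_points.items():
        path = out / f"ccdf_{key}.tsv"
        pd.DataFrame(points, columns=["x", "p"]).to_csv(path, sep="\t", index=False)
        written.append(path)

    path = out / "run.json"
    _write_json(
        path,
        {
            "seed": results.config.seed,
            "config_hash": _config_hash(results.config),
            "n_bootstrap": results.config.n_bootstrap,
            "min_tail": results.config.min_tail,
            "errors": results.errors,
            "outputs": [p.name for p in written],
        },
    )
    written.append(path)
    return written
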