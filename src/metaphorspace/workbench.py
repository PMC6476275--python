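"""End-to-end experiment orchestration.

One config drives the whole protocol: build (or load) the PMI base
space, project a subspace for every rated dyad under each selection
technique, extract the 48 geometric features, and evaluate them against
the graded judgements and the three-way class — full-feature
leave-one-out models, single-feature correlation rankings, and the
VIF-constrained reduced models — optionally alongside the static-
embedding cosine baseline. All artifacts are written to an output
directory with a manifest recording the config hash and library
versions; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baseline import baseline_evaluate, dyad_cosines, load_embeddings
from .corpus import PMIConfig, PMIMatrix, build_vocabulary, clean_corpus, compute_pmi, count_cooccurrences
from .errors import MetaphorspaceError, ValidationError
from .geometry import FEATURE_NAMES, extract_features
from .regress import (
    CVResult,
    FeatureMatrix,
    RATING_COLUMNS,
    accuracy_metric,
    fisher_r_to_z_test,
    load_dyads,
    loo_linear_cv,
    loo_logistic_ovr_cv,
    ols_coefficients,
    permutation_test,
    rank_single_features,
    standardize_features,
    vif_select,
)
from .subspace import DyadQuery, Subspace, TECHNIQUES

__all__ = ["RunConfig", "run_experiment", "build_matrix_from_corpus"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    dyads_csv: str
    out_dir: str
    corpus_path: str | None = None
    matrix_dir: str | None = None
    embeddings_path: str | None = None
    techniques: tuple[str, ...] = TECHNIQUES
    k: int = 200
    window: int = 2
    smoothing_a: float = 10_000.0
    vocab_size: int = 200_000
    min_context_count: int = 1
    fac: float = 2.0
    max_features: int = 5
    n_perm: int = 10_000
    seed: int = 0
    strict: bool = False

    def __post_init__(self):
        if (self.corpus_path is None) == (self.matrix_dir is None):
            raise ValidationError("exactly one of corpus_path/matrix_dir is required")
        unknown = set(self.techniques) - set(TECHNIQUES)
        if unknown:
            raise ValidationError(f"unknown techniques: {sorted(unknown)}")
        for name in ("dyads_csv", "corpus_path", "matrix_dir", "embeddings_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "techniques" in raw:
            raw["techniques"] = tuple(raw["techniques"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_matrix_from_corpus(
    corpus_path: str | Path,
    vocab_size: int,
    window: int = 2,
    smoothing_a: float = 10_000.0,
    min_context_count: int = 1,
):
    """Corpus file -> (Vocabulary, PMIMatrix)."""
    with open(corpus_path, encoding="utf-8") as fh:
        text = fh.read()
    sentences = list(clean_corpus(text))
    vocab = build_vocabulary(sentences, vocab_size)
    table = count_cooccurrences(sentences, vocab, window, min_context_count)
    return vocab, compute_pmi(table, PMIConfig(smoothing_a=smoothing_a))


def features_for_dyads(
    pmi: PMIMatrix,
    dyads: pd.DataFrame,
    technique: str,
    k: int,
    strict: bool = False,
) -> pd.DataFrame:
    """An n x 48 feature table for every dyad, indexed by (verb, noun)."""
    rows = []
    index = []
    with warnings.catch_warnings():
        if not strict:
            warnings.simplefilter("ignore")
        for _, row in dyads.iterrows():
            q = DyadQuery(row["verb"], row["noun"], technique, k)
            s = Subspace.project(pmi, q, strict=strict)
            rows.append(extract_features(s, strict=strict))
            index.append((row["verb"], row["noun"]))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["verb", "noun"]),
        columns=list(FEATURE_NAMES),
    )


def _evaluate_technique(
    feats: pd.DataFrame,
    dyads: pd.DataFrame,
    technique: str,
    fac: float,
    max_features: int,
) -> dict:
    """Full-feature, single-feature and VIF-reduced evaluations."""
    F = standardize_features(FeatureMatrix(feats.reset_index(drop=True)))
    out: dict = {
        "technique": technique,
        "n": len(dyads),
        "full": {},
        "vif": {},
        "_labels": dyads["class"].to_numpy(),
    }

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rating in RATING_COLUMNS:
            y = dyads[rating].to_numpy(dtype=np.float64)
            out["full"][rating] = loo_linear_cv(F, y, rating, technique)
        out["full"]["class"] = loo_logistic_ovr_cv(
            F, dyads["class"].to_numpy(), technique
        )

        rankings = {
            rating: rank_single_features(F, dyads[rating].to_numpy(dtype=np.float64))
            for rating in RATING_COLUMNS
        }
        out["rankings"] = rankings

        selections = {}
        for rating in RATING_COLUMNS:
            sel = vif_select(rankings[rating], F, fac=fac, max_features=max_features)
            selections[rating] = sel
            Fsel = FeatureMatrix(F.data[sel.selected].copy(), standardized=True)
            y = dyads[rating].to_numpy(dtype=np.float64)
            out["vif"][rating] = loo_linear_cv(Fsel, y, rating, technique)
        out["selections"] = selections
        out["coefficients"] = {
            rating: ols_coefficients(
                FeatureMatrix(F.data[selections[rating].selected].copy(), True),
                dyads[rating].to_numpy(dtype=np.float64),
            )
            for rating in RATING_COLUMNS
        }
        # the class model reuses the metaphoricity-selected feature set
        # (metaphoricity is the class-defining gradient)
        Fcls = FeatureMatrix(
            F.data[selections["metaphoricity"].selected].copy(), True
        )
        out["vif"]["class"] = loo_logistic_ovr_cv(
            Fcls, dyads["class"].to_numpy(), technique
        )
    return out


def run_experiment(cfg: RunConfig) -> dict:
    """Run the full protocol and write the report bundle.

    Returns the in-memory results dict (one entry per technique, plus
    optional baseline results and the manifest).
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str):
        logger.info(msg)
        log_lines.append(msg)

    if cfg.matrix_dir:
        pmi = PMIMatrix.load(cfg.matrix_dir)
        log(f"loaded matrix from {cfg.matrix_dir}")
    else:
        _, pmi = build_matrix_from_corpus(
            cfg.corpus_path, cfg.vocab_size, cfg.window,
            cfg.smoothing_a, cfg.min_context_count,
        )
        log(f"built matrix from {cfg.corpus_path}: "
            f"{len(pmi.row_words)} rows x {len(pmi.col_words)} contexts")

    dyads = load_dyads(cfg.dyads_csv)
    in_vocab = dyads.apply(
        lambda r: r["verb"] in pmi and r["noun"] in pmi, axis=1
    )
    excluded = dyads.loc[~in_vocab, ["verb", "noun"]].to_records(index=False).tolist()
    if excluded:
        log(f"excluded {len(excluded)} out-of-vocabulary dyads")
    dyads = dyads.loc[in_vocab].reset_index(drop=True)
    if len(dyads) < 6:
        raise MetaphorspaceError("too few in-vocabulary dyads to evaluate")

    results: dict = {}
    for technique in cfg.techniques:
        try:
            feats = features_for_dyads(pmi, dyads, technique, cfg.k, cfg.strict)
        except MetaphorspaceError as e:
            raise MetaphorspaceError(
                f"stage=features technique={technique}: {e}"
            ) from e
        ok = ~feats.isna().any(axis=1).to_numpy()
        n_bad = int((~ok).sum())
        if n_bad:
            log(f"{technique}: dropped {n_bad} dyads with undefined features")
        results[technique] = _evaluate_technique(
            feats.loc[ok], dyads.loc[ok].reset_index(drop=True),
            technique, cfg.fac, cfg.max_features,
        )
        results[technique]["features"] = feats

    if cfg.embeddings_path:
        emb = load_embeddings(cfg.embeddings_path)
        with_cos = dyad_cosines(emb, dyads, strict=cfg.strict)
        results["w2v"] = {"results": baseline_evaluate(with_cos), "data": with_cos}
        log(f"baseline evaluated on {len(with_cos)} dyads")

    _write_reports(cfg, results, excluded, out_dir, log_lines)
    return results


# ----------------------------------------------------------------------
# report writing


def _summary_frame(cfg: RunConfig, results: dict) -> pd.DataFrame:
    rows = []
    for technique in cfg.techniques:
        r = results[technique]
        for mode in ("full", "vif"):
            for target in (*RATING_COLUMNS, "class"):
                cv: CVResult = r[mode][target]
                nf = (
                    len(r["selections"]["metaphoricity" if target == "class" else target].selected)
                    if mode == "vif"
                    else len(FEATURE_NAMES)
                )
                rows.append(
                    {
                        "technique": technique,
                        "mode": mode,
                        "target": target,
                        "metric": cv.kind,
                        "score": cv.summary,
                        "n_features": nf,
                        "n_dyads": r["n"],
                    }
                )
    if "w2v" in results:
        for target, cv in results["w2v"]["results"].items():
            rows.append(
                {
                    "technique": "w2v",
                    "mode": "cosine",
                    "target": target,
                    "metric": cv.kind,
                    "score": cv.summary,
                    "n_features": 1,
                    "n_dyads": len(results["w2v"]["data"]),
                }
            )
    return pd.DataFrame(rows)


def _significance_frame(cfg: RunConfig, results: dict) -> pd.DataFrame:
    rows = []
    techs = list(cfg.techniques)
    for i, a in enumerate(techs):
        for b in techs[i + 1 :]:
            na, nb = results[a]["n"], results[b]["n"]
            for rating in RATING_COLUMNS:
                ra = results[a]["full"][rating].summary
                rb = results[b]["full"][rating].summary
                z, p = fisher_r_to_z_test(ra, na, rb, nb)
                rows.append(
                    {"comparison": f"{a} vs {b}", "target": rating,
                     "test": "fisher_r_to_z", "statistic": z, "p": p}
                )
            la, lb = results[a]["_labels"], results[b]["_labels"]
            # paired sign-flip comparison requires both techniques to
            # have evaluated the identical dyad rows
            if cfg.n_perm > 0 and len(la) == len(lb) and (la == lb).all():
                pa = results[a]["full"]["class"].predictions
                pb = results[b]["full"]["class"].predictions
                p = permutation_test(
                    accuracy_metric, pa, la, pb,
                    n_perm=cfg.n_perm, seed=cfg.seed,
                )
                rows.append(
                    {"comparison": f"{a} vs {b}", "target": "class",
                     "test": "permutation", "statistic": float("nan"), "p": p}
                )
    return pd.DataFrame(rows)


def _write_reports(cfg, results, excluded, out_dir: Path, log_lines):
    for technique in cfg.techniques:
        r = results[technique]
        feats: pd.DataFrame = r["features"]
        feats.to_csv(out_dir / f"features_{technique}.csv")

        ranked = pd.DataFrame(
            {
                rating: pd.Series(dict(r["rankings"][rating]))
                for rating in RATING_COLUMNS
            }
        ).loc[list(FEATURE_NAMES)]
        ranked.index.name = "feature"
        ranked.to_csv(out_dir / f"single_features_{technique}.csv")

        vif_rows = []
        for rating in RATING_COLUMNS:
            sel = r["selections"][rating]
            coefs = r["coefficients"][rating]
            for rank, name in enumerate(sel.selected, start=1):
                vif_rows.append(
                    {
                        "target": rating,
                        "rank": rank,
                        "feature": name,
                        "coefficient": coefs[name],
                        "r_squared_at_selection": sel.r_squared[name],
                    }
                )
        pd.DataFrame(vif_rows).to_csv(out_dir / f"vif_{technique}.csv", index=False)

    summary = _summary_frame(cfg, results)
    summary.to_csv(out_dir / "summary.csv", index=False)

    try:
        sig = _significance_frame(cfg, results)
        sig.to_csv(out_dir / "significance.csv", index=False)
    except ValueError:
        logger.warning("significance tests skipped (degenerate correlations)")

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "package_version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "excluded_dyads": [list(t) for t in excluded],
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out_dir / "run.log", "w", encoding="utf-8") as fh:
        fh.write("".join(line + "\n" for line in log_lines))
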