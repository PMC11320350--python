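"""File formats, run configuration, and end-to-end orchestration.

All tables are tab-delimited UTF-8 with a header row; missing values are
empty strings.  The model and run summary are YAML.  A single integer seed
in the config governs the whole run; per-stage seeds are derived by fixed
offsets and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clock, coxnet, enrichment, preprocess, validation
from .containers import ProteinMatrix
from .simulate import DiseaseSpec, SimulationParams, generate_cohort

__all__ = [
    "read_protein_matrix",
    "write_protein_matrix",
    "read_cohort",
    "write_cohort",
    "read_gmt",
    "write_gmt",
    "RunConfig",
    "run_all",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- tables


def write_protein_matrix(matrix: ProteinMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index=True, na_rep="")


def read_protein_matrix(path, gene_map=None) -> ProteinMatrix:
    """Tab-delimited matrix: first column participant ids, header protein ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate participant ids")
    if df.columns.has_duplicates or any(c.endswith((".1", ".2")) and c.rsplit(".", 1)[0] in df.columns
                                        for c in df.columns):
        raise ValueError(f"{path}: duplicate protein ids")
    return ProteinMatrix(df, gene_map)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=True, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate participant ids")
    return df


# ---------------------------------------------------------------- GMT


def read_gmt(path, background_size: int = enrichment.DEFAULT_BACKGROUND,
             background=None) -> enrichment.GeneSetCollection:
    """GMT: one set per line — name, description, tab-separated symbols.

    Symbols are uppercased; duplicates within a set are collapsed.
    """
    sets: dict[str, frozenset[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{i}: GMT line needs name, description, >=1 symbol")
        name = fields[0]
        symbols = frozenset(s.strip().upper() for s in fields[2:] if s.strip())
        if not symbols:
            raise ValueError(f"{path}:{i}: set {name!r} has no symbols")
        sets[name] = symbols
    return enrichment.GeneSetCollection(sets, background_size=background_size,
                                        background=background)


def write_gmt(collection: enrichment.GeneSetCollection, path,
              description: str = "na") -> None:
    lines = []
    for name, members in collection.sets.items():
        lines.append("\t".join([name, description, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- config


@dataclass
class RunConfig:
    """End-to-end run configuration.

    Either ``simulate`` holds generator parameters, or ``matrix_path`` and
    ``cohort_path`` point at existing tables.
    """

    seed: int = 0
    simulate: SimulationParams | None = None
    matrix_path: str | None = None
    cohort_path: str | None = None
    gene_sets_path: str | None = None
    split_fraction: float = 0.7
    impute_k: int = 10
    missing_threshold: float = 0.5
    lambda_policy: str = "auto"  # "auto" (CV) or a fixed value as float/str
    cv_folds: int = 10
    n_lambdas: int = 30
    horizon: float = 10.0
    unpenalized_age: bool = False
    outcomes: tuple[str, ...] = ()  # diseases; mortality is always analyzed
    background_size: int = enrichment.DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.impute_k < 1:
            raise ValueError("impute_k must be >= 1")
        if not (0 < self.missing_threshold <= 1):
            raise ValueError("missing_threshold must lie in (0, 1]")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.simulate is None:
            for fld in ("matrix_path", "cohort_path"):
                p = getattr(self, fld)
                if p is None:
                    raise ValueError(f"config field {fld!r} required when not simulating")
                if not Path(p).exists():
                    raise FileNotFoundError(f"config field {fld!r}: no such file {p!r}")
        if self.gene_sets_path is not None and not Path(self.gene_sets_path).exists():
            raise FileNotFoundError(
                f"config field 'gene_sets_path': no such file {self.gene_sets_path!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            diseases = tuple(
                DiseaseSpec(name=d["name"], base_hazard=float(d["base_hazard"]),
                            age_effect=float(d.get("age_effect", 0.0)),
                            protein_effects={int(k): float(v)
                                             for k, v in (d.get("protein_effects") or {}).items()})
                for d in sim.pop("diseases", [])
            )
            sim = SimulationParams(disease_specs=diseases, **sim)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "outcomes" in raw:
            raw["outcomes"] = tuple(raw["outcomes"])
        return cls(simulate=sim, **raw)


# ---------------------------------------------------------------- run_all


def run_all(config: RunConfig, out_dir) -> dict:
    """Simulate/load -> preprocess -> split -> train -> score -> validate -> enrich.

    Writes a machine-readable bundle (tab-delimited tables + YAML summary +
    plain-text log) into ``out_dir`` and returns the summary dict.
    Identical config + seed reproduce the bundle byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []

    def stage(msg: str) -> None:
        lines.append(msg)
        log.info(msg)

    seed = int(config.seed)
    # ---- data
    if config.simulate is not None:
        params = config.simulate
        if params.seed != seed:
            from dataclasses import replace

            params = replace(params, seed=seed)
        cohort, matrix, truth = generate_cohort(params)
        stage(f"simulate: n={len(cohort)} proteins={matrix.values.shape[1]} seed={seed}")
        write_cohort(cohort, out / "cohort.tsv")
        write_protein_matrix(matrix, out / "matrix.tsv")
        (out / "ground_truth.yaml").write_text(yaml.safe_dump({
            "causal_proteins": truth.causal_proteins,
            "causal_betas": [float(b) for b in truth.causal_betas],
            "gompertz_shape": params.gompertz_shape,
            "gompertz_lograte": params.gompertz_lograte,
            "age_beta": params.age_beta,
        }, sort_keys=True))
        outcomes = tuple(s.name for s in params.disease_specs)
    else:
        cohort = read_cohort(config.cohort_path)
        matrix = read_protein_matrix(config.matrix_path)
        stage(f"load: n={len(cohort)} proteins={matrix.values.shape[1]}")
        outcomes = tuple(config.outcomes)

    # ---- preprocess
    matrix, removed = preprocess.filter_high_missingness(matrix, config.missing_threshold)
    stage(f"filter: removed={len(removed)} kept={matrix.values.shape[1]}")
    matrix = preprocess.knn_impute(matrix, k=config.impute_k)
    stage(f"impute: k={config.impute_k}")

    # ---- split
    train_ids, test_ids = clock.split_cohort(cohort.index, config.split_fraction,
                                             seed=seed + 1)
    stage(f"split: train={len(train_ids)} test={len(test_ids)} seed={seed + 1}")
    X_train = pd.concat([cohort.loc[train_ids, ["age"]], matrix.values.loc[train_ids]], axis=1)
    t_train = cohort.loc[train_ids, "time_death"].to_numpy()
    d_train = cohort.loc[train_ids, "died"].to_numpy()
    stage(f"train events: {int(d_train.sum())} of {len(train_ids)}")

    # ---- train
    unpen = ["age"] if config.unpenalized_age else None
    if config.lambda_policy == "auto":
        lam, cv_table = coxnet.select_lambda(X_train, t_train, d_train,
                                             n_folds=config.cv_folds,
                                             n_lambdas=config.n_lambdas,
                                             seed=seed + 2, unpenalized=unpen)
        if cv_table is not None:
            cv_table.to_csv(out / "cv_path.tsv", sep="\t", index=False)
        stage(f"lambda: cv-selected {lam:.6g} (folds={config.cv_folds}, seed={seed + 2})")
    else:
        lam = float(config.lambda_policy)
        stage(f"lambda: fixed {lam:.6g}")
    path = coxnet.fit_lasso_cox(X_train, t_train, d_train, lambdas=[lam], unpenalized=unpen)
    selected = [c for c in path[0].selected if c != "age"]
    stage(f"lasso: selected {len(selected)} proteins at lambda={lam:.6g}")
    pac = clock.build_pac(X_train, t_train, d_train, selected, horizon_k=config.horizon)
    pac.save(out / "model.yaml")

    # ---- score
    scores = clock.score_cohort(pac, matrix, cohort.loc[test_ids])
    scores.to_csv(out / "scores.tsv", sep="\t")
    stage(f"score: test n={len(scores)} mean proteomic age "
          f"{scores['proteomic_age'].mean():.2f}")

    # ---- validate
    data = cohort.loc[test_ids].join(scores)
    tiers = validation.default_tiers()
    assoc = validation.run_association_suite(data, "deviation",
                                             ["mortality", *outcomes], tiers)
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
    comp = validation.compare_models_c(data, ["age", "proteomic_age"],
                                       "time_death", "died")
    comp.to_csv(out / "concordance.tsv", sep="\t")
    corr = validation.correlation_panel(data, ["age", "proteomic_age"], "spearman")
    corr.to_csv(out / "correlations.tsv", sep="\t")
    stage(f"validate: {len(assoc)} association tests; "
          f"spearman(age, proteomic_age)={corr.loc['age', 'proteomic_age']:.3f}")

    # ---- enrich
    enr_rows = None
    if config.gene_sets_path is not None:
        collection = read_gmt(config.gene_sets_path, background_size=config.background_size)
        test_vals = matrix.values.loc[test_ids]
        transformed = test_vals.apply(lambda c: preprocess.inverse_normal(c), axis=0)
        covs = data[["age", "sex", "education", "deprivation", "smoking", "bmi"]]
        assoc_prot = enrichment.associate_proteins(data["deviation"].to_numpy(),
                                                   transformed, covs)
        assoc_prot.to_csv(out / "protein_associations.tsv", sep="\t")
        sig = assoc_prot.index[assoc_prot["bonferroni_p"] < 0.05]
        genes = enrichment.map_proteins_to_genes(sig, matrix.gene_map)
        stage(f"enrich: {len(sig)} significant proteins -> {len(genes)} genes")
        if genes:
            enr_rows = enrichment.run_gene_set_analysis(genes, collection)
            enr_rows.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            stage(f"enrich: {int((enr_rows['bonferroni_p'] < 0.05).sum())} sets "
                  f"Bonferroni-significant of {len(enr_rows)} tested")

    summary = {
        "seed": seed,
        "n_participants": int(len(cohort)),
        "n_proteins": int(matrix.values.shape[1]),
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "lambda": float(lam),
        "n_selected_proteins": len(selected),
        "mean_proteomic_age_test": float(scores["proteomic_age"].mean()),
        "spearman_age": float(corr.loc["age", "proteomic_age"]),
        "n_association_tests": int(len(assoc)),
        "n_enriched_sets": None if enr_rows is None
        else int((enr_rows["bonferroni_p"] < 0.05).sum()),
    }
    (out / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
    (out / "run.log").write_text("\n".join(lines) + "\n")
    return summary
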