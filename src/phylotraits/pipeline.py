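"""End-to-end study orchestration.

Loads one or two phylogenies plus a species-by-trait table, applies the
declared transforms and coding rules, and emits: a phylogenetic-signal
battery (Pagel's lambda for continuous traits including the residual of
the antennal allometry, Fritz-Purvis D for binary traits), PGLS model
batteries with AIC/evidence-ratio comparison against a null, and Fitch
parsimony origin counts for the binary traits.  Species in the tree and
the table are reconciled by intersection with logged drop counts; results
are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pgls import compare_to_null, fit_pgls, residuals_of
from .phylo import PhyloTree, count_origins_fitch, parse_newick, prune_to, vcv
from .signal import fit_d, fit_lambda
from .simulate import BINARY_COLS, COUNT_COLS, RAW_CONTINUOUS_COLS, SPECIES_COL

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "BatterySpec",
    "load_traits",
    "load_tree",
    "reconcile",
    "signal_battery",
    "model_battery",
    "origin_counts",
    "run_full",
]

#: raw column -> derived log column
LOG_TRANSFORMS = {
    "body_length_mm": "log_body_length",
    "antennal_area_mm2": "log_antennal_area",
    "n_host_species": "log_n_host_species",
}

#: continuous traits analysed for lambda, in report order; the residual of
#: the antennal allometry is computed on the fly from a PGLS fit
DEFAULT_CONTINUOUS = (
    "log_body_length",
    "residual_log_antennal_area",
    "log_n_host_species",
    "n_host_orders",
    "n_plant_genera",
)

DEFAULT_BINARY = tuple(BINARY_COLS)

DEFAULT_PREDICTORS = (
    "log_n_host_species",
    "n_host_orders",
    "n_plant_genera",
    "parasitoid",
    "egg_parasitoid",
    "specialist",
    "para_hemiptera",
    "para_sternorrhyncha",
    "para_other_hemiptera",
    "para_diptera",
    "para_lepidoptera",
    "para_coleoptera",
    "para_hymenoptera",
)


@dataclass
class BatterySpec:
    """One table of single-predictor PGLS models sharing a response.

    With a ``covariate`` (e.g. body size in antennal models) every model
    includes it, and the null is the covariate-only model rather than the
    intercept-only one.
    """

    name: str
    response: str
    predictors: Tuple[str, ...] = DEFAULT_PREDICTORS
    covariate: Optional[str] = None


def default_batteries() -> List[BatterySpec]:
    body_preds = tuple(p for p in DEFAULT_PREDICTORS)
    antenna_preds = tuple(p for p in DEFAULT_PREDICTORS)
    return [
        BatterySpec(name="body_size", response="log_body_length", predictors=body_preds),
        BatterySpec(
            name="antennal_size",
            response="log_antennal_area",
            predictors=antenna_preds,
            covariate="log_body_length",
        ),
    ]


@dataclass
class StudyConfig:
    """Configuration of a full study run.

    ``trees`` maps a name to a Newick path; two entries give dual-phylogeny
    mode (the whole analysis is repeated per tree and matrices are never
    mixed across trees).
    """

    trees: Dict[str, str]
    traits: str
    continuous_traits: Tuple[str, ...] = DEFAULT_CONTINUOUS
    binary_traits: Tuple[str, ...] = DEFAULT_BINARY
    batteries: List[BatterySpec] = field(default_factory=default_batteries)
    n_sim: int = 1000
    seed: int = 0
    log_base: str = "e"
    alpha: float = 0.05
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        batteries = [BatterySpec(**b) for b in raw.pop("batteries", [])]
        cfg = cls(**{k: v for k, v in raw.items() if k != "batteries"})
        if batteries:
            cfg.batteries = batteries
        cfg.continuous_traits = tuple(cfg.continuous_traits)
        cfg.binary_traits = tuple(cfg.binary_traits)
        return cfg

    def to_dict(self) -> dict:
        return {
            "trees": dict(self.trees),
            "traits": self.traits,
            "continuous_traits": list(self.continuous_traits),
            "binary_traits": list(self.binary_traits),
            "batteries": [
                {
                    "name": b.name,
                    "response": b.response,
                    "predictors": list(b.predictors),
                    "covariate": b.covariate,
                }
                for b in self.batteries
            ],
            "n_sim": self.n_sim,
            "seed": self.seed,
            "log_base": self.log_base,
            "alpha": self.alpha,
            "outdir": self.outdir,
        }


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def load_tree(path: str) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def load_traits(path: str, log_base: str = "e") -> pd.DataFrame:
    """Load a trait table, validate 0/1 columns, and add log columns.

    Natural log by default (``log_base`` may be "e" or "10"; slopes, R2 and
    evidence ratios are base-invariant, intercepts are not).  Raises on
    non-positive values in log-transformed columns, naming the species.
    """
    df = pd.read_csv(path)
    if SPECIES_COL not in df.columns:
        raise ValueError(f"trait table must have a {SPECIES_COL!r} column")
    df[SPECIES_COL] = df[SPECIES_COL].astype(str).str.strip()
    if df[SPECIES_COL].duplicated().any():
        dups = df[SPECIES_COL][df[SPECIES_COL].duplicated()].tolist()
        raise ValueError(f"duplicate species in trait table: {dups[:5]}")
    df = df.set_index(SPECIES_COL, drop=False)

    for col in BINARY_COLS:
        if col not in df.columns:
            continue
        vals = df[col].dropna().unique()
        bad = [v for v in vals if v not in (0, 1)]
        if bad:
            raise ValueError(f"non-binary values in 0/1 column {col!r}: {bad[:5]}")

    log_fn = np.log if log_base == "e" else np.log10
    for raw, logged in LOG_TRANSFORMS.items():
        if raw not in df.columns:
            continue
        nonpos = df.index[df[raw] <= 0].tolist()
        if nonpos:
            raise ValueError(
                f"non-positive values in {raw!r} cannot be log transformed "
                f"(species: {nonpos[:5]})"
            )
        df[logged] = log_fn(df[raw].astype(float))
    return df


def reconcile(tree: PhyloTree, traits: pd.DataFrame) -> Tuple[PhyloTree, pd.DataFrame]:
    """Intersect tree tips with trait-table species, logging drop counts."""
    tips = set(tree.tip_labels)
    rows = set(traits.index)
    common = tips & rows
    if len(common) < 4:
        raise ValueError(f"only {len(common)} species shared between tree and table")
    dropped_tips = len(tips - common)
    dropped_rows = len(rows - common)
    if dropped_tips or dropped_rows:
        logger.info(
            "reconciliation dropped %d tree tips and %d table rows",
            dropped_tips, dropped_rows,
        )
    if dropped_tips:
        tree = prune_to(tree, common)
    table = traits.loc[tree.tip_labels]
    return tree, table


# ---------------------------------------------------------------------------
# Signal battery
# ---------------------------------------------------------------------------

ALLOMETRY = ("log_antennal_area", "log_body_length")  # response, predictor


def _residual_antennal(tree: PhyloTree, traits: pd.DataFrame) -> pd.Series:
    resp, pred = ALLOMETRY
    sub = traits[[resp, pred]].dropna()
    sub_tree, sub = (tree, sub) if len(sub) == len(traits) else reconcile(tree, sub)
    y = sub[resp].to_numpy(dtype=float)
    x = sub[pred].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub)), x])
    fit = fit_pgls(sub_tree, y, X, lambda_mode="ML", names=("intercept", pred))
    return pd.Series(residuals_of(fit), index=list(fit.species))


def signal_battery(
    tree: PhyloTree,
    traits: pd.DataFrame,
    continuous: Sequence[str] = DEFAULT_CONTINUOUS,
    binary: Sequence[str] = DEFAULT_BINARY,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Phylogenetic-signal table: lambda per continuous trait (LR test
    against lambda = 0), D per binary trait (test against D = 1).

    The residual-antennal-area row first fits the allometric PGLS of log
    antennal area on log body length (ML lambda) and takes the phylogenetic
    signal of its response-scale residuals.  Constant traits are flagged
    "unidentifiable" rather than raising.
    """
    tree, traits = reconcile(tree, traits)
    rng = np.random.default_rng(seed)
    rows = []
    for trait in continuous:
        row = {"trait": trait, "statistic": "lambda", "n_sim": np.nan}
        try:
            if trait == "residual_log_antennal_area":
                series = _residual_antennal(tree, traits)
                sub_tree = tree if len(series) == len(traits) else prune_to(tree, set(series.index))
            else:
                if trait not in traits.columns:
                    raise KeyError(f"trait column {trait!r} not found")
                series = traits[trait].dropna().astype(float)
                sub_tree = tree if len(series) == len(traits) else prune_to(tree, set(series.index))
            fit = fit_lambda(sub_tree, series)
            row.update(
                estimate=fit.lambda_hat, p_value=fit.p_value,
                significant=fit.p_value < alpha, n=fit.n, note="",
            )
        except (ValueError, KeyError) as exc:
            row.update(estimate=np.nan, p_value=np.nan, significant=False,
                       n=np.nan, note=f"unidentifiable: {exc}")
        rows.append(row)
    for trait in binary:
        row = {"trait": trait, "statistic": "D", "n_sim": n_sim}
        fit_seed = int(rng.integers(0, 2**31 - 1))
        try:
            if trait not in traits.columns:
                raise KeyError(f"trait column {trait!r} not found")
            series = traits[trait].dropna().astype(int)
            sub_tree = tree if len(series) == len(traits) else prune_to(tree, set(series.index))
            res = fit_d(sub_tree, series, n_sim=n_sim, seed=fit_seed)
            row.update(
                estimate=res.D, p_value=res.p_random,
                significant=res.p_random < alpha, n=sub_tree.n_tips, note="",
            )
        except (ValueError, KeyError) as exc:
            row.update(estimate=np.nan, p_value=np.nan, significant=False,
                       n=np.nan, note=f"unidentifiable: {exc}")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model batteries
# ---------------------------------------------------------------------------


def model_battery(
    tree: PhyloTree, traits: pd.DataFrame, spec: BatterySpec
) -> pd.DataFrame:
    """One single-predictor PGLS (ML lambda) per listed predictor, compared
    by AIC against the null (intercept-only, or covariate-only when the
    battery declares a covariate).

    The evidence ratio is shown (``er_display``) only for models whose AIC
    beats the null, mirroring comparative-table convention; the numeric
    value is always retained in ``er``.
    """
    tree, traits = reconcile(tree, traits)
    base_cols = [spec.response] + ([spec.covariate] if spec.covariate else [])
    complete = traits[base_cols].dropna()
    if len(complete) < len(traits):
        logger.info("dropped %d rows incomplete for %s",
                    len(traits) - len(complete), base_cols)
    base_tree = tree if len(complete) == len(traits) else prune_to(tree, set(complete.index))
    base_tbl = traits.loc[base_tree.tip_labels]

    y = base_tbl[spec.response].to_numpy(dtype=float)
    n = len(y)
    if spec.covariate:
        cov = base_tbl[spec.covariate].to_numpy(dtype=float)
        X_null = np.column_stack([np.ones(n), cov])
        null_names = ("intercept", spec.covariate)
    else:
        X_null = np.ones((n, 1))
        null_names = ("intercept",)
    V = vcv(base_tree)
    null_fit = fit_pgls(V, y, X_null, lambda_mode="ML", names=null_names)

    rows = []
    for pred in spec.predictors:
        row = {"predictor": pred, "n": n}
        try:
            if pred not in base_tbl.columns:
                raise KeyError(f"predictor column {pred!r} not found")
            x = base_tbl[pred].to_numpy(dtype=float)
            if np.isnan(x).any():
                mask = ~np.isnan(x)
                sub_tree = prune_to(base_tree, set(np.array(base_tree.tip_labels)[mask]))
                sub_tbl = base_tbl.loc[sub_tree.tip_labels]
                xv = sub_tbl[pred].to_numpy(dtype=float)
                yv = sub_tbl[spec.response].to_numpy(dtype=float)
                Vm = vcv(sub_tree)
                covv = (sub_tbl[spec.covariate].to_numpy(dtype=float)
                        if spec.covariate else None)
                row["n"] = len(yv)
            else:
                xv, yv, Vm = x, y, V
                covv = (base_tbl[spec.covariate].to_numpy(dtype=float)
                        if spec.covariate else None)
            if np.allclose(xv, xv[0]):
                raise ValueError("predictor is constant after row filtering")
            cols = [np.ones(len(yv))]
            names = ["intercept"]
            if covv is not None:
                cols.append(covv)
                names.append(spec.covariate)
            cols.append(xv)
            names.append(pred)
            fit = fit_pgls(Vm, yv, np.column_stack(cols), lambda_mode="ML",
                           names=tuple(names))
            comp = compare_to_null(null_fit.aic, fit.aic)
            beta_idx = len(names) - 1
            row.update(
                lambda_=fit.lambda_, beta=fit.params[beta_idx], se=fit.se[beta_idx],
                r2=fit.r2, aic=fit.aic, loglik=fit.loglik, k=fit.k,
                er=comp.er,
                er_display=f"{comp.er:.2f}" if comp.better_than_null else "-",
                note="",
            )
        except (ValueError, KeyError) as exc:
            row.update(lambda_=np.nan, beta=np.nan, se=np.nan, r2=np.nan,
                       aic=np.nan, loglik=np.nan, k=np.nan, er=np.nan,
                       er_display="-", note=f"skipped: {exc}")
        rows.append(row)

    null_beta = null_fit.params[1] if spec.covariate else np.nan
    null_se = null_fit.se[1] if spec.covariate else np.nan
    rows.append({
        "predictor": "null" if not spec.covariate else f"null ({spec.covariate} only)",
        "n": n, "lambda_": null_fit.lambda_, "beta": null_beta, "se": null_se,
        "r2": null_fit.r2, "aic": null_fit.aic, "loglik": null_fit.loglik,
        "k": null_fit.k, "er": 1.0, "er_display": "1", "note": "",
    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Origin counts and the full run
# ---------------------------------------------------------------------------


def origin_counts(
    tree: PhyloTree, traits: pd.DataFrame, binary: Sequence[str] = DEFAULT_BINARY
) -> pd.DataFrame:
    """Fitch parsimony minimum number of state changes per binary trait."""
    tree, traits = reconcile(tree, traits)
    rows = []
    for trait in binary:
        if trait not in traits.columns:
            continue
        states = {sp: int(v) for sp, v in traits[trait].dropna().items()}
        sub_tree = (tree if len(states) == len(traits)
                    else prune_to(tree, set(states)))
        rows.append({"trait": trait,
                     "min_changes": count_origins_fitch(sub_tree, states),
                     "n_ones": int(sum(states.values())),
                     "n": len(states)})
    return pd.DataFrame(rows)


def run_full(config: StudyConfig) -> Path:
    """Run the complete study for each configured phylogeny.

    Writes, per tree: ``signal_<name>.csv``, ``battery_<battery>_<name>.csv``
    and ``origins_<name>.csv``, plus a run log and the resolved config.
    Reruns with the same config and seed are byte-identical.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traits = load_traits(config.traits, log_base=config.log_base)
    log_lines = [
        f"phylotraits {__version__}",
        f"seed: {config.seed}",
        f"log base: {config.log_base}",
        f"n_sim: {config.n_sim}",
    ]
    for name, tree_path in config.trees.items():
        tree = load_tree(tree_path)
        rtree, rtraits = reconcile(tree, traits)
        log_lines.append(
            f"tree {name}: {rtree.n_tips} species after reconciliation "
            f"({tree.n_tips} tips in tree, {len(traits)} rows in table)"
        )
        try:
            sig = signal_battery(
                rtree, rtraits, config.continuous_traits, config.binary_traits,
                n_sim=config.n_sim, seed=config.seed, alpha=config.alpha,
            )
            sig.to_csv(outdir / f"signal_{name}.csv", index=False)
        except Exception as exc:  # partial outputs are retained
            log_lines.append(f"ERROR in signal battery for {name}: {exc}")
            logger.exception("signal battery failed for %s", name)
        for battery in config.batteries:
            try:
                tbl = model_battery(rtree, rtraits, battery)
                tbl.to_csv(outdir / f"battery_{battery.name}_{name}.csv", index=False)
            except Exception as exc:
                log_lines.append(f"ERROR in battery {battery.name} for {name}: {exc}")
                logger.exception("battery %s failed for %s", battery.name, name)
        try:
            org = origin_counts(rtree, rtraits, config.binary_traits)
            org.to_csv(outdir / f"origins_{name}.csv", index=False)
        except Exception as exc:
            log_lines.append(f"ERROR in origin counts for {name}: {exc}")
            logger.exception("origin counts failed for %s", name)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    (outdir / "config_resolved.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    return outdir
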