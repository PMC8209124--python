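"""File formats, run configuration and the end-to-end pipeline.

Formats (all plain text):
  * individual records — CSV with header ``id,birth,first_detect,
    last_detect,origin,fate,sex``; an empty ``birth`` field means unknown;
  * life tables — two-column (age, lx) CSV/TSV, '#' comments ignored;
  * MCMC chains — CSV with ``chain,iter`` plus one column per parameter;
  * fit summaries — JSON (see :class:`paceshape.bayes.FitSummary`);
  * run manifest — JSON with the seed, package version and config hash.

Every writer stamps a ``# paceshape`` comment header carrying the seed and
config hash so outputs are traceable to the run that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import (
    FitSummary,
    MCMCConfig,
    PosteriorChains,
    PriorSpec,
    fit_zoo,
    run_mcmc,
    summarize,
)
from .cohorts import CohortConfig, IndividualRecord, OutMigrationModel, simulate_cohort
from .landscape import (
    collinearity,
    fit_genus_line,
    parameter_trajectory,
    rank_parameter_changes,
)
from .sensitivity import gradient_vector
from .siler import PARAM_NAMES, QuadratureConfig, SilerParams, pace_shape_summary

__all__ = [
    "read_records",
    "write_records",
    "read_lifetable",
    "write_chains",
    "read_chains",
    "write_fit_summary",
    "read_fit_summary",
    "RunConfig",
    "load_config",
    "pipeline",
]

RECORD_COLUMNS = ["id", "birth", "first_detect", "last_detect", "origin", "fate", "sex"]
_FLOAT_FMT = "%.17g"  # shortest exact round-trip needs up to 17 significant digits


def _header(seed: Optional[int] = None, config_hash: Optional[str] = None) -> str:
    parts = [f"# paceshape v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return " ".join(parts) + "\n"


def write_records(
    path, records: Sequence[IndividualRecord], seed: Optional[int] = None,
    config_hash: Optional[str] = None,
) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "birth": [r.birth for r in records],
            "first_detect": [r.first_detect for r in records],
            "last_detect": [r.last_detect for r in records],
            "origin": [r.origin for r in records],
            "fate": [r.fate for r in records],
            "sex": [r.sex for r in records],
        }
    )
    with open(path, "w") as fh:
        fh.write(_header(seed, config_hash))
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_records(path) -> List[IndividualRecord]:
    """Read and validate an individual-record CSV.

    Violations (last detection before first, birth after first detection,
    bad enums) raise ValueError naming the offending record id.
    """
    df = pd.read_csv(path, comment="#", dtype={"id": str}, float_precision="round_trip")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record file {path} missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        birth = None if pd.isna(row["birth"]) else float(row["birth"])
        records.append(
            IndividualRecord(
                id=str(row["id"]),
                birth=birth,
                first_detect=float(row["first_detect"]),
                last_detect=float(row["last_detect"]),
                origin=str(row["origin"]),
                fate=str(row["fate"]),
                sex="unknown" if pd.isna(row["sex"]) else str(row["sex"]),
            )
        )
    return records


def read_lifetable(path) -> Tuple[np.ndarray, np.ndarray]:
    """Read a two-column (age, lx) table; '#' comments ignored.

    lx must be non-increasing; a rise raises ValueError naming the age.
    """
    df = pd.read_csv(path, comment="#", sep=None, engine="python", header=None)
    if df.shape[1] < 2:
        raise ValueError(f"life table {path} must have two columns (age, lx)")
    first = df.iloc[0]
    try:
        float(first[0]), float(first[1])
    except (TypeError, ValueError):  # header row
        df = df.iloc[1:]
    ages = df.iloc[:, 0].astype(float).to_numpy()
    lx = df.iloc[:, 1].astype(float).to_numpy()
    rising = np.diff(lx) > 1e-12
    if rising.any():
        raise ValueError(f"lx increases at age {ages[int(np.argmax(rising)) + 1]}")
    if np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing")
    return ages, lx


def write_chains(path, chains: PosteriorChains, config_hash: Optional[str] = None) -> None:
    df = chains.to_dataframe()
    with open(path, "w") as fh:
        fh.write(_header(chains.seed, config_hash))
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_chains(path) -> PosteriorChains:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    names = tuple(c for c in df.columns if c not in ("chain", "iter"))
    chains_ids = sorted(df["chain"].unique())
    arrs = [df[df["chain"] == c][list(names)].to_numpy() for c in chains_ids]
    n = min(a.shape[0] for a in arrs)
    draws = np.stack([a[:n] for a in arrs])
    return PosteriorChains(
        draws=draws, param_names=names, acceptance={}, n_records=0
    )


def write_fit_summary(path, summary: FitSummary, seed: Optional[int] = None,
                      config_hash: Optional[str] = None) -> None:
    payload = summary.to_dict()
    payload["_meta"] = {"version": __version__, "seed": seed, "config": config_hash}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_summary(path) -> FitSummary:
    payload = json.loads(Path(path).read_text())
    payload.pop("_meta", None)
    return FitSummary.from_dict(payload)


# ---------------------------------------------------------------------------
# run configuration and pipeline

@dataclasses.dataclass
class RunConfig:
    """Declarative description of a pipeline run.

    ``stages`` is any subset of {"simulate", "fit", "sensitivity",
    "landscape"} executed in that order; later stages read the outputs of
    earlier ones (or pre-existing files given in ``records_path`` etc.).
    """

    out_dir: str = "results"
    stages: Tuple[str, ...] = ("simulate", "fit", "sensitivity", "landscape")
    seed: int = 0
    # simulate
    cohort: Optional[CohortConfig] = None
    records_path: Optional[str] = None
    # fit
    mcmc: MCMCConfig = dataclasses.field(default_factory=MCMCConfig)
    priors: PriorSpec = dataclasses.field(default_factory=PriorSpec)
    zoo_mode: bool = False
    alphas: Optional[Dict[str, float]] = None
    # numerics
    quad: QuadratureConfig = dataclasses.field(default_factory=QuadratureConfig)
    # landscape: list of fit-summary JSON paths grouped as one genus
    genus_summaries: Tuple[str, ...] = ()

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_PRIOR_KEYS = ("mean", "sd", "lower", "upper")


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML or JSON file (keys mirror the fields)."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    kwargs: dict = {}
    for key in ("out_dir", "seed", "records_path", "zoo_mode", "alphas"):
        if key in raw:
            kwargs[key] = raw[key]
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    if "genus_summaries" in raw:
        kwargs["genus_summaries"] = tuple(raw["genus_summaries"])
    if "mcmc" in raw:
        kwargs["mcmc"] = MCMCConfig(**raw["mcmc"])
    if "quad" in raw:
        kwargs["quad"] = QuadratureConfig(**raw["quad"])
    if "priors" in raw:
        from .bayes import PriorEntry, _default_entries

        entries = _default_entries()
        pr = dict(raw["priors"])
        pi_beta = tuple(pr.pop("pi_beta", (1.0, 1.0)))
        for name, spec in pr.items():
            base = entries[name]
            merged = {k: spec.get(k, getattr(base, k)) for k in _PRIOR_KEYS}
            entries[name] = PriorEntry(**merged)
        kwargs["priors"] = PriorSpec(entries=entries, pi_beta=pi_beta)
    if "cohort" in raw:
        co = dict(raw["cohort"])
        co["params"] = SilerParams(**co["params"])
        co["outmig_natal"] = OutMigrationModel(**co["outmig_natal"])
        if co.get("outmig_immigrant"):
            co["outmig_immigrant"] = OutMigrationModel(**co["outmig_immigrant"])
        if "study_window" in co:
            co["study_window"] = tuple(co["study_window"])
        kwargs["cohort"] = CohortConfig(**co)
    return RunConfig(**kwargs)


def pipeline(config: RunConfig) -> int:
    """Run the requested stage sequence; returns 0 on success.

    Outputs land in ``config.out_dir``; a ``manifest.json`` records the
    seed, version and config hash.  On a stage failure the partially
    written outputs of that stage are renamed with a ``.partial`` suffix
    and a nonzero status is returned.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": h,
        "stages": list(config.stages),
        "outputs": {},
    }
    records: Optional[List[IndividualRecord]] = None
    chains: Optional[PosteriorChains] = None
    summary: Optional[FitSummary] = None

    def fail(stage: str, err: Exception, partial: List[Path]) -> int:
        for p in partial:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        manifest["error"] = f"{stage}: {err}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return 1

    for stage in config.stages:
        if stage == "simulate":
            target = out / "records.csv"
            try:
                if config.cohort is None:
                    raise ValueError("simulate stage requires a cohort config")
                cohort = dataclasses.replace(config.cohort, seed=config.seed)
                records = simulate_cohort(cohort)
                write_records(target, records, seed=config.seed, config_hash=h)
            except Exception as err:
                return fail(stage, err, [target])
            manifest["outputs"]["records"] = str(target)
        elif stage == "fit":
            t_chain, t_summ = out / "chains.csv", out / "fit_summary.json"
            try:
                if records is None:
                    if config.records_path is None:
                        raise ValueError("fit stage needs simulated records or records_path")
                    records = read_records(config.records_path)
                mcmc = dataclasses.replace(config.mcmc, seed=config.seed)
                if config.zoo_mode:
                    chains = fit_zoo(records, config.priors, mcmc)
                else:
                    chains = run_mcmc(records, config.priors, mcmc, alphas=config.alphas)
                summary = summarize(chains, config.quad)
                write_chains(t_chain, chains, config_hash=h)
                write_fit_summary(t_summ, summary, seed=config.seed, config_hash=h)
            except Exception as err:
                return fail(stage, err, [t_chain, t_summ])
            manifest["outputs"]["chains"] = str(t_chain)
            manifest["outputs"]["fit_summary"] = str(t_summ)
        elif stage == "sensitivity":
            target = out / "sensitivities.csv"
            try:
                if summary is None:
                    raise ValueError("sensitivity stage needs a fitted model (run fit first)")
                rows = []
                gv = gradient_vector(summary.theta_hat, config.quad)
                for name in PARAM_NAMES:
                    rows.append(
                        {
                            "param": name,
                            "value": getattr(summary.theta_hat, name),
                            "e_theta": gv[name].e_theta,
                            "eps_theta": gv[name].eps_theta,
                        }
                    )
                with open(target, "w") as fh:
                    fh.write(_header(config.seed, h))
                    pd.DataFrame(rows).to_csv(fh, index=False, float_format=_FLOAT_FMT)
            except Exception as err:
                return fail(stage, err, [target])
            manifest["outputs"]["sensitivities"] = str(target)
        elif stage == "landscape":
            t_line, t_theta = out / "genus_line.csv", out / "path_integrals.csv"
            try:
                summaries = [read_fit_summary(p) for p in config.genus_summaries]
                if len(summaries) < 2:
                    raise ValueError("landscape stage needs >= 2 fit summaries (genus_summaries)")
                pts = [(s.e_hat, s.epsilon_hat) for s in summaries]
                weights = [1.0 / s.e_se if s.e_se > 0 else 1.0 for s in summaries]
                plist = [s.theta_hat for s in summaries]
                line = fit_genus_line(pts, weights, plist)
                traj = parameter_trajectory(line)
                rank, errors = rank_parameter_changes(line, traj, config.quad)
                coll = {
                    name: float(
                        np.median(
                            [collinearity(line, gradient_vector(p, config.quad)[name])
                             for p in plist]
                        )
                    )
                    for name in PARAM_NAMES
                }
                with open(t_line, "w") as fh:
                    fh.write(_header(config.seed, h))
                    pd.DataFrame(
                        [
                            {
                                "beta0": line.beta0,
                                "beta1": line.beta1,
                                "slope_se": line.slope_se,
                                "p_value": line.p_value,
                                "e_min": line.e_range[0],
                                "e_max": line.e_range[1],
                            }
                        ]
                    ).to_csv(fh, index=False, float_format=_FLOAT_FMT)
                rows = [
                    {"param": k, "abs_theta": v, "log10_abs_theta": np.log10(v),
                     "collinearity": coll[k], "singular": ""}
                    for k, v in rank
                ] + [
                    {"param": k, "abs_theta": np.nan, "log10_abs_theta": np.nan,
                     "collinearity": coll[k], "singular": str(e)}
                    for k, e in errors.items()
                ]
                with open(t_theta, "w") as fh:
                    fh.write(_header(config.seed, h))
                    pd.DataFrame(rows).to_csv(fh, index=False, float_format=_FLOAT_FMT)
            except Exception as err:
                return fail(stage, err, [t_line, t_theta])
            manifest["outputs"]["genus_line"] = str(t_line)
            manifest["outputs"]["path_integrals"] = str(t_theta)
        else:
            return fail(stage, ValueError(f"unknown stage {stage!r}"), [])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return 0
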