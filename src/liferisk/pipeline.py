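"""End-to-end orchestration: generate/load -> classify -> estimate ->
simulate -> cross-validate -> report.

A :class:`RunConfig` (flat YAML document) fully determines a run; together
with its seed it determines every numeric output. Each stage's outputs are
plain CSV files plus a JSON manifest recording the configuration hash,
package and library versions, stage timings, record counts, and surfaced
warnings (for example zero-at-risk fallback ages).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .apc import cohort_lifetime_risk, fit_apc, rate_cells_from_histories
from .classify import apply_exclusions, filter_cohort, resolve_state_histories
from .competing import modified_km_lifetime_risk
from .estimation import crude_incidence, estimate_transitions
from .registry import GeneratorConfig, generate_registry
from .simulate import (
    SimulatedCohort,
    bootstrap_lifetime,
    life_years,
    lifetime_quantities_exact,
    resample_table,
    simulate_cohort,
    validate_against_observed,
)
from .states import State
from .sullivan import build_life_table, mortality_from_cohort, prevalence_from_cohort
from .transitions import TransitionTable

ORIGINS = (State.PRE, State.NORMO)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    out_dir: str | None = None
    registry_csv: str | None = None           # load instead of generate
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    prediabetes_definition: str = "any"
    min_entry_age: float = 0.0
    min_followup: float = 0.0
    period_window: tuple[int, int] | None = None
    simulation_n: int = 500_000
    simulation_start_age: int = 0
    index_ages: tuple[int, ...] = (20, 40, 60)
    sex_strata: tuple[str, ...] = ("pooled", "M", "F")
    run_mkm: bool = True
    run_sullivan: bool = True
    run_apc: bool = False
    run_validation: bool = True
    bootstrap_reps: int = 0                   # 0 disables CI computation
    bootstrap_n_sim: int = 100_000
    mortality_substitution_csv: str | None = None
    apc_cohorts: tuple[int, ...] = tuple(range(1900, 1981, 10))
    #: last calendar year with complete death linkage; defaults to the
    #: generator's period end for generated registries
    linkage_end_year: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.prediabetes_definition not in ("any", "fpg_only", "hba1c_only"):
            raise ValueError(f"bad prediabetes_definition: {cfg.prediabetes_definition!r}")
        if cfg.period_window is not None:
            cfg.period_window = tuple(cfg.period_window)  # type: ignore[assignment]
        cfg.index_ages = tuple(cfg.index_ages)
        cfg.sex_strata = tuple(cfg.sex_strata)
        cfg.apc_cohorts = tuple(cfg.apc_cohorts)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle.

    The bundle maps stage names to DataFrames/objects: ``records`` (if
    generated), ``histories``, ``tables`` (per sex), ``estimates``,
    ``crude``, ``mkm``, ``sullivan``, ``validation``, ``apc_risks``, and
    ``manifest``. When ``config.out_dir`` is set every table is also written
    as CSV; outputs of completed stages survive a later stage failure.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config), "config_hash": config.config_hash(),
        "liferisk_version": __version__,
        "numpy_version": np.__version__, "pandas_version": pd.__version__,
        "stages": {}, "warnings": [],
    }
    bundle: dict = {"manifest": manifest}

    def _stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                _write_manifest(manifest, out_dir)
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return wrap

    @_stage("ingest")
    def _():
        if config.registry_csv:
            records = pd.read_csv(config.registry_csv)
        else:
            gen = GeneratorConfig(**{"seed": config.seed, **config.generator})
            records = generate_registry(gen)
            bundle["generator_config"] = gen
        bundle["records"] = records
        manifest["stages"]["ingest_n_records"] = int(len(records))

    @_stage("classify")
    def _():
        records = apply_exclusions(bundle["records"])
        linkage_year = config.linkage_end_year
        if linkage_year is None and "generator_config" in bundle:
            linkage_year = bundle["generator_config"].period_range[1]
        histories = resolve_state_histories(records, config.prediabetes_definition,
                                            linkage_end_year=linkage_year)
        histories = filter_cohort(histories, config.min_followup, config.min_entry_age)
        bundle["histories"] = histories
        if out_dir:
            histories.to_csv(out_dir / "histories.csv", index=False)

    @_stage("crude_incidence")
    def _():
        rows = []
        for origin in ORIGINS:
            rate, n_events, py = crude_incidence(bundle["histories"], origin, State.DM)
            rows.append({"origin_state": origin.name, "rate_per_1000py": rate,
                         "n_events": n_events, "person_years": py})
        bundle["crude"] = pd.DataFrame(rows)
        if out_dir:
            bundle["crude"].to_csv(out_dir / "crude_incidence.csv", index=False)

    @_stage("estimate")
    def _():
        tables: dict[str, TransitionTable] = {}
        frames = []
        for sex in config.sex_strata:
            table = estimate_transitions(bundle["histories"], sex=sex,
                                         period=config.period_window)
            if config.mortality_substitution_csv:
                death = pd.read_csv(config.mortality_substitution_csv)
                q = np.zeros((table.max_age + 1, 3))
                for s in (State.NORMO, State.PRE, State.DM):
                    sub = death[death["state"] == s.name]
                    q[sub["age"].to_numpy(int), int(s)] = sub["death_prob"].to_numpy(float)
                table = table.substitute_mortality(q)
            tables[sex] = table
            frames.append(table.to_frame())
        bundle["tables"] = tables
        if out_dir:
            pd.concat(frames).to_csv(out_dir / "transitions.csv", index=False)

    @_stage("simulate")
    def _():
        cohorts: dict[str, SimulatedCohort] = {}
        rows = []
        for i, sex in enumerate(config.sex_strata):
            table = bundle["tables"][sex]
            cohort = simulate_cohort(table, config.simulation_n,
                                     seed=config.seed + 1000 + i,
                                     start_age=config.simulation_start_age)
            cohorts[sex] = cohort
            cis = {}
            if config.bootstrap_reps > 0:
                cis = bootstrap_lifetime(
                    table, list(config.index_ages), list(ORIGINS),
                    n_boot=config.bootstrap_reps, n_sim=config.bootstrap_n_sim,
                    seed=config.seed + 2000 + i)
            for origin in ORIGINS:
                for age in config.index_ages:
                    est = life_years(cohort, age, origin)
                    est.ci95 = cis.get((age, origin), {})
                    row = {"sex": sex, **est.as_row()}
                    exact = lifetime_quantities_exact(table, age, origin)
                    row.update({f"{k}_exact": v for k, v in exact.items()})
                    rows.append(row)
        bundle["cohorts"] = cohorts
        bundle["estimates"] = pd.DataFrame(rows)
        if out_dir:
            bundle["estimates"].to_csv(out_dir / "lifetime_estimates.csv", index=False)

    if config.run_mkm:
        @_stage("modified_km")
        def _():
            rows = []
            for sex in config.sex_strata:
                sel = None if sex == "pooled" else sex
                for origin in ORIGINS:
                    for age in config.index_ages:
                        res = modified_km_lifetime_risk(bundle["histories"], origin,
                                                        age, sex=sel)
                        rows.append({"sex": sex, "origin_state": origin.name,
                                     "index_age": age, "risk": res["risk"],
                                     "risk_lo": res["ci95"][0],
                                     "risk_hi": res["ci95"][1],
                                     "n_at_entry": res["n_at_entry"],
                                     "unstable": res["unstable"]})
            bundle["mkm"] = pd.DataFrame(rows)
            if out_dir:
                bundle["mkm"].to_csv(out_dir / "modified_km.csv", index=False)

    if config.run_sullivan:
        @_stage("sullivan")
        def _():
            frames = []
            for sex in config.sex_strata:
                cohort = bundle["cohorts"][sex]
                q = mortality_from_cohort(cohort)
                prev = prevalence_from_cohort(cohort)
                start = cohort.start_age
                lt = build_life_table(np.nan_to_num(q[start:], nan=1.0),
                                      prev[start:], max_age=cohort.max_age - start)
                lt["age"] = lt["age"] + start
                lt.insert(0, "sex", sex)
                frames.append(lt)
            bundle["sullivan"] = pd.concat(frames, ignore_index=True)
            if out_dir:
                bundle["sullivan"].to_csv(out_dir / "sullivan.csv", index=False)

    if config.run_validation:
        @_stage("validate")
        def _():
            frames = []
            for sex in config.sex_strata:
                sel = bundle["histories"] if sex == "pooled" else \
                    bundle["histories"][bundle["histories"]["sex"] == sex]
                cmp = validate_against_observed(bundle["cohorts"][sex], sel)
                if len(cmp):
                    cmp.insert(0, "sex", sex)
                    frames.append(cmp)
            bundle["validation"] = (pd.concat(frames, ignore_index=True)
                                    if frames else pd.DataFrame())
            if out_dir:
                bundle["validation"].to_csv(out_dir / "validation.csv", index=False)

    if config.run_apc:
        @_stage("apc")
        def _():
            hist = bundle["histories"]
            inc = fit_apc(rate_cells_from_histories(hist, State.PRE, "dm"),
                          outcome="dm_incidence_from_pre")
            mort = fit_apc(rate_cells_from_histories(hist, State.NORMO, "death"),
                           outcome="mortality")
            rows = []
            for cohort_year in config.apc_cohorts:
                for age in config.index_ages:
                    risk = cohort_lifetime_risk(inc, mort, cohort_year, age)
                    rows.append({"birth_cohort": cohort_year, "index_age": age,
                                 "origin_state": "PRE", "risk": risk})
            bundle["apc_risks"] = pd.DataFrame(rows)
            bundle["apc_models"] = {"incidence": inc, "mortality": mort}
            if out_dir:
                bundle["apc_risks"].to_csv(out_dir / "apc_cohort_risks.csv", index=False)

    _write_manifest(manifest, out_dir)
    return bundle


def _write_manifest(manifest: dict, out_dir: Path | None) -> None:
    if out_dir:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)


def compare_populations(
    bundle_a: dict,
    bundle_b: dict,
    substitute: bool = False,
    n_boot: int = 100,
    seed: int = 0,
    sexes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Between-population differences in lifetime risk, with paired bootstrap
    intervals.

    Risks are computed exactly by matrix propagation from each bundle's
    estimated transition tables; when ``substitute`` is true, population A's
    tables are first given population B's mortality schedule, isolating the
    contribution of differential survival to the risk gap.
    """
    if sexes is None:
        sexes = tuple(s for s in bundle_a["tables"] if s in bundle_b["tables"])
        if not sexes:
            raise ValueError("no shared sex strata between bundles")
    ages_a = set(bundle_a["estimates"]["index_age"])
    ages_b = set(bundle_b["estimates"]["index_age"])
    index_ages = sorted(ages_a & ages_b)
    if not index_ages:
        raise ValueError(
            f"no shared index ages: {sorted(ages_a)} vs {sorted(ages_b)}")
    rng = np.random.default_rng(seed)

    def _risks(ta: TransitionTable, tb: TransitionTable) -> dict:
        ta_eff = ta.substitute_mortality(tb.death_probabilities()) if substitute else ta
        out = {}
        for origin in ORIGINS:
            for age in index_ages:
                ra = lifetime_quantities_exact(ta_eff, age, origin)["lifetime_risk"]
                rb = lifetime_quantities_exact(tb, age, origin)["lifetime_risk"]
                out[(origin, age)] = (ra, rb)
        return out

    rows = []
    for sex in sexes:
        ta, tb = bundle_a["tables"][sex], bundle_b["tables"][sex]
        point = _risks(ta, tb)
        boots: dict[tuple, list[float]] = {k: [] for k in point}
        for _ in range(n_boot):
            ra = resample_table(ta, rng)
            rb = resample_table(tb, rng)
            for k, (xa, xb) in _risks(ra, rb).items():
                boots[k].append(xa - xb)
        for (origin, age), (ra, rb) in point.items():
            diffs = np.asarray(boots[(origin, age)])
            lo, hi = (np.percentile(diffs, [2.5, 97.5]) if diffs.size
                      else (np.nan, np.nan))
            rows.append({"sex": sex, "origin_state": origin.name, "index_age": age,
                         "risk_a": ra, "risk_b": rb, "difference": ra - rb,
                         "difference_lo": float(lo), "difference_hi": float(hi),
                         "substituted_mortality": substitute})
    return pd.DataFrame(rows)
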