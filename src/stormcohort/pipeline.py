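"""End-to-end orchestration: exposure -> cohort -> epi -> model -> sensitivity.

``run_pipeline`` executes every stage deterministically for a given
(inputs, config, seed), writes all tabular outputs as headered CSVs with a
sidecar schema description, and records a JSON manifest (config hash, seed,
package version, row counts per stage).  Reruns with the same config and
seed produce byte-identical outputs.  A stage failure aborts the run with a
stage-named diagnostic and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import pathlib

import numpy as np
import pandas as pd

from . import __version__, cohort as cohort_mod
from . import descriptive_epi, sensitivity, survival_model
from .config import RunConfig, SimConfig, dump_yaml
from .errors import StormCohortError
from .exposure import build_exposure_table

SCHEMAS = {
    "exposure.csv": "area_id, cumulative_mm, cumulative_in, distance_km, approach_time, approach_date, exposed — one row per area",
    "exclusions.json": "exclusion ledger: counts by rule in application order (age, missingness, relocation)",
    "table1.csv": "cohort characteristics by exposure status with t/Mann-Whitney/chi-squared tests",
    "epi_measures_by_subgroup.csv": "unadjusted rates, relative risk, attributable fraction and attributable deaths per subgroup",
    "km_curves.csv": "group, time, survival, cum_incidence, at_risk — product-limit curves by exposure",
    "hazard_ratios.csv": "subgroup, n, events, hr, ci_low, ci_high, theta, converged — adjusted frailty-Cox exposure HRs",
    "evalues.csv": "subgroup, hr, e_point, e_ci — unmeasured-confounding sensitivity",
    "morans_i.csv": "model, I, expected, z, p, scheme — residual spatial autocorrelation",
    "relocation_comparison.csv": "subgroup HRs excluding vs including relocated beneficiaries",
    "manifest.json": "run metadata: config hash, seed, version, row counts",
}


def analyze(inputs: dict, config: RunConfig | None = None) -> dict:
    """Run every analysis stage on in-memory inputs; returns artifact dict."""
    config = config or RunConfig()
    artifacts = {}
    counts = {}

    def stage(name, fn):
        try:
            return fn()
        except StormCohortError as exc:
            raise StormCohortError(f"stage {name!r} failed: {exc}") from exc

    if "exposure" in inputs:
        exposure_table = inputs["exposure"]
    else:
        exposure_table = stage(
            "exposure",
            lambda: build_exposure_table(
                inputs["areas"],
                inputs["stations"],
                inputs["daily_rain"],
                inputs["track"],
                step_minutes=config.step_minutes,
                threshold_mm=config.threshold_mm,
                window_offsets=config.window_offsets,
                utc_offset_hours=config.utc_offset_hours,
                power=config.idw_power,
                radius_km=config.idw_radius_km,
                min_stations=config.idw_min_stations,
                max_radius_km=config.idw_max_radius_km,
            ),
        )
    artifacts["exposure"] = exposure_table
    counts["areas"] = len(exposure_table)

    built = stage(
        "cohort",
        lambda: cohort_mod.build_cohort(
            inputs["beneficiaries"],
            inputs["survival"],
            exposure_table,
            include_relocated=config.include_relocated,
        ),
    )
    artifacts["cohort"] = built.data
    artifacts["exclusions"] = built.exclusions
    counts["beneficiaries_input"] = built.exclusions["input"]
    counts["cohort_retained"] = built.n

    df = built.data
    specs = survival_model.default_subgroups()
    masks = {s.name: np.asarray(s.predicate(df), dtype=bool) for s in specs}

    artifacts["table1"] = stage("table_one", lambda: descriptive_epi.table_one(df))
    artifacts["epi_measures_by_subgroup"] = stage(
        "epi_measures", lambda: descriptive_epi.epi_measures_by_subgroup(df, masks)
    )
    artifacts["km_curves"] = stage(
        "km_curves", lambda: descriptive_epi.km_curves_by_exposure(df)
    )
    hr_table = stage("survival_model", lambda: survival_model.subgroup_hrs(df, specs))
    artifacts["hazard_ratios"] = hr_table

    ev_rows = []
    for row in hr_table.itertuples():
        if getattr(row, "note", "") or not np.isfinite(getattr(row, "hr", np.nan)):
            continue
        res = sensitivity.evalue(row.hr, row.ci_low, row.ci_high)
        ev_rows.append(
            {"subgroup": row.subgroup, "hr": row.hr,
             "e_point": res.e_point, "e_ci": res.e_ci}
        )
    artifacts["evalues"] = pd.DataFrame(ev_rows)

    overall_fit = stage(
        "overall_fit", lambda: survival_model.fit_adjusted(df)
    )
    area_resid = sensitivity.residuals_by_area(overall_fit, df)
    cents = inputs["areas"].set_index("area_id").loc[area_resid.index, ["lat", "lon"]]
    moran = stage(
        "morans_i",
        lambda: sensitivity.morans_i(
            area_resid.to_numpy(), centroids=cents, seed=config.seed
        ),
    )
    artifacts["morans_i"] = pd.DataFrame(
        [{"model": "overall", "I": moran.I, "expected": moran.expected,
          "z": moran.z, "p": moran.p, "scheme": moran.scheme}]
    )

    artifacts["relocation_comparison"] = stage(
        "relocation",
        lambda: sensitivity.relocation_sensitivity(
            inputs["beneficiaries"], inputs["survival"], exposure_table
        ),
    )
    artifacts["counts"] = counts
    return artifacts


def run_pipeline(
    inputs: dict,
    out_dir,
    config: RunConfig | None = None,
    sim_config: SimConfig | None = None,
) -> pathlib.Path:
    """Analyze and write all artifacts to ``out_dir``; returns the directory."""
    config = config or RunConfig()
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        artifacts = analyze(inputs, config)
        for name in (
            "exposure",
            "cohort",
            "table1",
            "epi_measures_by_subgroup",
            "km_curves",
            "hazard_ratios",
            "evalues",
            "morans_i",
            "relocation_comparison",
        ):
            path = out / f"{name}.csv"
            artifacts[name].to_csv(path, index=False, float_format="%.10g")
            written.append(path)
        path = out / "exclusions.json"
        path.write_text(json.dumps(artifacts["exclusions"], indent=2))
        written.append(path)

        config_text = dump_yaml(config) + (dump_yaml(sim_config) if sim_config else "")
        manifest = {
            "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
            "seed": config.seed,
            "stormcohort_version": __version__,
            "row_counts": artifacts["counts"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "schemas.json").write_text(json.dumps(SCHEMAS, indent=2))
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return out
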