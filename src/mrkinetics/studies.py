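"""Packaged summary-statistic fixtures and end-to-end study reproductions.

The per-SNP exposure (coffee, cups/day) and outcome (cigarettes/day,
SD-cotinine) association tables ship with the package, so the headline
two-sample MR estimates can be recomputed with zero downloads.  Every results
document embeds the configuration, package version and input checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from importlib import resources

import pandas as pd

from . import __version__
from .exceptions import ValidationError
from .instruments import harmonize, parse_summary_table, select_model
from .mr import MRConfig, forest_table, run_two_sample_mr

FIXTURES = {
    "ccgc_exposure": "ccgc_coffee_exposure.tsv",
    "tag_cigarettes": "tag_cigarettes_outcome.tsv",
    "cotinine": "cotinine_outcome.tsv",
    "ukb_cigarettes": "ukb_cigarettes_outcome.tsv",
}


def fixture_path(name: str):
    if name not in FIXTURES:
        raise ValidationError(f"unknown fixture {name!r}; have {sorted(FIXTURES)}")
    return resources.files("mrkinetics.data") / FIXTURES[name]


def fixture_checksum(name: str) -> str:
    return hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()


def load_instrument_set(outcome_fixture: str):
    """Harmonized instrument set pairing the coffee exposure table with an outcome fixture."""
    exposure = parse_summary_table(fixture_path("ccgc_exposure"), phenotype="exposure")
    outcome = parse_summary_table(fixture_path(outcome_fixture), phenotype="outcome")
    return harmonize(exposure, outcome)


def _provenance(config: MRConfig, fixtures: list[str]) -> dict:
    return {
        "package": "mrkinetics",
        "version": __version__,
        "config": asdict(config),
        "inputs": {name: fixture_checksum(name) for name in fixtures},
    }


def _results_block(instrument_set, config: MRConfig) -> list[dict]:
    results = run_two_sample_mr(instrument_set, config)
    out = []
    i = 0
    for model in config.models:
        for method in config.methods:
            res = results[i]
            i += 1
            out.append({
                "model": model, "method": method,
                **res.to_dict(),
                "forest_table": forest_table(res).to_dict(orient="records"),
            })
    return out


def run_study1(config: MRConfig | None = None) -> dict:
    """Two-sample MR of coffee on smoking heaviness: cigarettes/day and cotinine.

    IVW for the 8/6/2-SNP models plus the weighted-median sensitivity
    analysis, for both outcome fixtures.
    """
    config = config or MRConfig()
    doc = {"study": "two-sample summary MR", "outcomes": {}}
    for label, fixture in (("cigarettes_per_day", "tag_cigarettes"),
                           ("cotinine_sd", "cotinine")):
        iset = load_instrument_set(fixture)
        doc["outcomes"][label] = _results_block(iset, config)
    doc["provenance"] = _provenance(config, ["ccgc_exposure", "tag_cigarettes", "cotinine"])
    return doc


def run_study3(config: MRConfig | None = None, cohort_spec=None) -> dict:
    """Biobank-style replication: Table-style two-sample IVW on the biobank
    outcome fixture, plus the full one-sample pipeline on a synthetic cohort.
    """
    from .onesample import (OneSampleConfig, compute_grs, filter_analysis_sample,
                            instrument_strength, observational_association,
                            one_sample_mr)
    from .simulate import CohortSpec, generate_cohort

    config = config or MRConfig(models=("8-SNP",))
    iset = load_instrument_set("ukb_cigarettes")
    doc = {"study": "biobank replication", "two_sample_style": _results_block(iset, config)}

    spec = cohort_spec or CohortSpec(seed=config.seed)
    cohort = filter_analysis_sample(generate_cohort(spec))
    scores = compute_grs(cohort)
    f_stat, r2 = instrument_strength(scores, cohort.exposure,
                                     cohort.covariates[["age", "sex"]])
    obs_beta, obs_se = observational_association(cohort, adjustments=("age", "sex"))
    mr_res = one_sample_mr(cohort, OneSampleConfig(covariates=("age", "sex"),
                                                   seed=config.seed))
    doc["synthetic_one_sample"] = {
        "n": cohort.n,
        "true_beta_causal": cohort.true_params["beta_causal"],
        "expected_observational_bias": cohort.true_params["observational_bias"],
        "grs_f_statistic": f_stat,
        "grs_r_squared": r2,
        "observational": {"beta": obs_beta, "se": obs_se},
        "mr": mr_res.to_dict(),
    }
    doc["provenance"] = _provenance(config, ["ccgc_exposure", "ukb_cigarettes"])
    return doc


def reproduce(seed: int = 20170712) -> dict:
    """Recompute every fixture-based headline quantity (plus power and the
    fractional-inhibition predictions) in one deterministic document."""
    from .kinetics import fractional_inhibition, mg_per_l_to_um, CAFFEIC_ACID_MW
    from .power import PowerSpec, mr_power

    config = MRConfig(seed=seed)
    doc = {
        "study1": run_study1(config),
        "study3": run_study3(MRConfig(models=("8-SNP",), seed=seed)),
        "power": {
            "r2_0.005": mr_power(PowerSpec(n=8072, r_squared=0.005, beta=1.5)),
            "r2_0.01": mr_power(PowerSpec(n=8072, r_squared=0.01, beta=1.5)),
        },
        "fractional_inhibition": {
            "caffeic_2_3_cups": fractional_inhibition(
                mg_per_l_to_um(1.11, CAFFEIC_ACID_MW), ki_uM=156.0),
            "caffeic_3_4_cups": fractional_inhibition(7.12, ki_uM=156.0),
        },
    }
    return doc


def write_results(doc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
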