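"""End-to-end orchestration: simulate or load a study, run arthroscopic QC,
preprocess, split at pony level, select wavelengths and train per
(parameter, variant), evaluate, and write the report bundle.

Information-flow rules: splits are assigned at pony granularity so no pony
spans groups; arthroscopic spectra never enter weight fitting (they appear
only inside the Model 1 selection criterion and in final evaluation); input
scaling and NRMSE ranges use in vitro data only.
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

from . import io as nio
from .evaluation import (
    aggregate_location_prediction,
    build_report,
    evaluate_set,
    group_comparison,
    group_summary,
    write_report_csv,
)
from .preprocess import arthroscopic_qc, preprocess_for
from .selection import VARIANTS, ForwardWavelengthSelector, ModelVariant
from .study import (
    CARTILAGE_PARAMETERS,
    PROPERTY_NAMES,
    AcquisitionConfig,
    EffectConfig,
    StudyData,
    StudyDesign,
    generate_study,
)

logger = logging.getLogger(__name__)

DEFAULT_PARAMETERS = tuple(p for p in PROPERTY_NAMES if p != "cartilage_thickness")
ANALYSIS_SETS = ("cal+val", "test", "arthroscopic")
_LOC_KEYS = ["pony", "joint", "location"]


class ConfigError(ValueError):
    """Invalid run configuration (raised before any compute)."""


@dataclass
class RunConfig:
    """Structured configuration of a full analysis run."""

    seed: int = 0
    output_dir: str = "nirscart_run"
    simulate: bool = True
    spectra_invitro: str | None = None
    spectra_arthro: str | None = None
    references: str | None = None
    design: dict = field(default_factory=dict)
    effect: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)
    split_fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    parameters: tuple[str, ...] = DEFAULT_PARAMETERS
    variants: tuple[str, ...] = ("Model1", "Model2", "Model3")
    arthro_keep: int = 8
    selection: dict = field(
        default_factory=lambda: {
            "stride": 8,
            "budget": 12,
            "patience": 4,
            "n_hidden": 3,
            "candidate_epochs": 15,
            "candidate_restarts": 1,
            "final_hidden_grid": (1, 2, 3, 4, 6, 8),
            "final_epochs": 80,
            "final_restarts": 2,
        }
    )

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")
        unknown = set(self.parameters) - set(PROPERTY_NAMES)
        if unknown:
            raise ConfigError(f"unknown parameters: {sorted(unknown)}")
        unknown_v = set(self.variants) - set(VARIANTS)
        if unknown_v:
            raise ConfigError(f"unknown variants: {sorted(unknown_v)}")

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("split_fractions", "parameters", "variants"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        names = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(d) - names
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**d)

    @staticmethod
    def from_file(path) -> "RunConfig":
        return RunConfig.from_dict(nio.load_config(path))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        d["parameters"] = list(self.parameters)
        d["variants"] = list(self.variants)
        d["selection"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.selection.items()
        }
        return d


def split_by_pony(
    references: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.6, 0.3, 0.1),
    seed: int = 0,
    locations_per_pony: int | None = None,
) -> dict[int, str]:
    """Assign ponies to calibration / validation / test.

    The test allocation draws from repair ponies only, preferring ponies
    with complete location coverage (none arthroscopically unreachable) so
    the test group is fully measured. Control ponies are spread over
    calibration and validation proportionally to the fractions. Deterministic
    under the seed; no pony spans two groups.
    """
    f_cal, f_val, f_test = fractions
    by_pony = references.groupby("pony").agg(
        group=("group", "first"), n_loc=("location", "size")
    )
    repair = list(by_pony.index[by_pony["group"] == "repair"])
    control = list(by_pony.index[by_pony["group"] == "control"])
    n = len(by_pony)
    if n < 3:
        raise ConfigError("need at least 3 ponies to split")
    n_test = max(1, round(f_test * n))
    if locations_per_pony is None:
        locations_per_pony = int(by_pony["n_loc"].max())
    full = [p for p in repair if by_pony.loc[p, "n_loc"] == locations_per_pony]

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B1]))
    test_pool = full if len(full) >= n_test else repair
    if len(test_pool) < n_test:
        raise ConfigError("not enough repair ponies for the test split")
    test = list(rng.choice(test_pool, size=n_test, replace=False))

    rest_repair = [p for p in repair if p not in test]
    n_ctl_cal = round(f_cal / (f_cal + f_val) * len(control))
    ctl = list(control)
    rng.shuffle(ctl)
    ctl_cal, ctl_val = ctl[:n_ctl_cal], ctl[n_ctl_cal:]
    n_cal_total = round(f_cal * n)
    n_rep_cal = max(0, n_cal_total - len(ctl_cal))
    rng.shuffle(rest_repair)
    rep_cal, rep_val = rest_repair[:n_rep_cal], rest_repair[n_rep_cal:]

    assignment: dict[int, str] = {}
    for p in rep_cal + ctl_cal:
        assignment[int(p)] = "cal"
    for p in rep_val + ctl_val:
        assignment[int(p)] = "val"
    for p in test:
        assignment[int(p)] = "test"
    if not any(v == "cal" for v in assignment.values()) or not any(
        v == "val" for v in assignment.values()
    ):
        raise ConfigError("split left calibration or validation empty")
    return assignment


def _loc_label(meta: pd.DataFrame) -> np.ndarray:
    return (
        meta["pony"].astype(str)
        + "-"
        + meta["joint"].astype(str)
        + "-"
        + meta["location"].astype(str)
    ).to_numpy()


@dataclass
class ModelData:
    """Per-(family, region) design matrices aligned with the reference table."""

    wavelengths: np.ndarray
    X_by_set: dict[str, np.ndarray]
    y_by_set: dict[str, np.ndarray]
    X_arthro: np.ndarray | None
    arthro_groups: np.ndarray | None
    y_arthro: dict | None


def _assemble(
    study: StudyData,
    arthro_retained,
    family: str,
    region: tuple[float, float],
    assignment: dict[int, str],
    parameter: str,
) -> ModelData:
    proc = preprocess_for(family, study.invitro, region).mean_by_location()
    merged = proc.meta.merge(study.references, on=_LOC_KEYS, suffixes=("", "_ref"))
    if len(merged) != len(proc.meta):
        raise ValueError("processed spectra and reference table do not align")
    y_all = merged[parameter].to_numpy(dtype=float)
    sets = merged["pony"].map(assignment).to_numpy()
    X_by_set = {name: proc.intensity[sets == name] for name in ("cal", "val", "test")}
    y_by_set = {name: y_all[sets == name] for name in ("cal", "val", "test")}

    X_arthro = arthro_groups = y_arthro = None
    if arthro_retained is not None and len(arthro_retained) > 0:
        proc_a = preprocess_for(family, arthro_retained, region)
        X_arthro = proc_a.intensity
        arthro_groups = _loc_label(proc_a.meta)
        ref = study.references
        y_arthro = dict(zip(_loc_label(ref), ref[parameter].to_numpy(dtype=float)))
    return ModelData(
        wavelengths=proc.wavelengths,
        X_by_set=X_by_set,
        y_by_set=y_by_set,
        X_arthro=X_arthro,
        arthro_groups=arthro_groups,
        y_arthro=y_arthro,
    )


def fit_parameter_variant(
    study: StudyData,
    arthro_retained,
    parameter: str,
    variant: ModelVariant | str,
    assignment: dict[int, str],
    selection_params: dict | None = None,
    random_state: int | None = None,
) -> tuple[ForwardWavelengthSelector, ModelData]:
    """Select wavelengths and train the final model for one target property
    and model variant."""
    variant = VARIANTS[variant] if isinstance(variant, str) else variant
    family = "cartilage" if parameter in CARTILAGE_PARAMETERS else "bone"
    data = _assemble(study, arthro_retained, family, variant.region, assignment,
                     parameter)
    reference_range = float(np.ptp(np.concatenate(list(data.y_by_set.values()))))
    params = dict(selection_params or {})
    if isinstance(params.get("final_hidden_grid"), list):
        params["final_hidden_grid"] = tuple(params["final_hidden_grid"])
    selector = ForwardWavelengthSelector(
        variant=variant, random_state=random_state, **params
    )
    needs_arthro = variant.criterion == "test_plus_arthro"
    selector.fit(
        data.X_by_set["cal"],
        data.y_by_set["cal"],
        data.X_by_set["val"],
        data.y_by_set["val"],
        data.X_by_set["test"],
        data.y_by_set["test"],
        wavelengths=data.wavelengths,
        reference_range=reference_range,
        X_arthro=data.X_arthro if needs_arthro else None,
        arthro_groups=data.arthro_groups if needs_arthro else None,
        y_arthro=data.y_arthro if needs_arthro else None,
    )
    return selector, data


def _region_label(region: tuple[float, float]) -> str:
    return f"{region[0]:.2f}-{region[1]:.2f}"


def evaluate_parameter_variant(
    selector: ForwardWavelengthSelector,
    data: ModelData,
    parameter: str,
    variant: ModelVariant,
    include_arthro: bool | None = None,
) -> list[dict]:
    """Evaluation-report rows for the three analysis sets.

    Arthroscopic evaluation applies to NIR-region variants only (the wide
    region overlaps the arthroscope-light band); pass ``include_arthro`` to
    override.
    """
    if include_arthro is None:
        include_arthro = variant.region[0] >= 0.75 and data.X_arthro is not None
    reference_range = selector.reference_range_
    base = {
        "parameter": parameter,
        "variant": variant.name,
        "region_um": _region_label(variant.region),
        "n_variables": selector.n_variables_,
    }
    rows = []
    y_cv = np.concatenate([data.y_by_set["cal"], data.y_by_set["val"]])
    pred_cv = np.concatenate(
        [selector.predict(data.X_by_set["cal"]), selector.predict(data.X_by_set["val"])]
    )
    rows.append(
        {**base, "set": "cal+val", **evaluate_set(y_cv, pred_cv, reference_range)}
    )
    rows.append(
        {
            **base,
            "set": "test",
            **evaluate_set(
                data.y_by_set["test"],
                selector.predict(data.X_by_set["test"]),
                reference_range,
            ),
        }
    )
    if include_arthro and data.X_arthro is not None and len(data.X_arthro):
        preds = selector.predict(data.X_arthro)
        y_true, y_pred = [], []
        for g in pd.unique(data.arthro_groups):
            agg = aggregate_location_prediction(preds[data.arthro_groups == g])
            if np.isfinite(agg) and g in data.y_arthro:
                y_true.append(data.y_arthro[g])
                y_pred.append(agg)
        if len(y_true) >= 4:
            rows.append(
                {
                    **base,
                    "set": "arthroscopic",
                    **evaluate_set(y_true, y_pred, reference_range),
                }
            )
        else:
            logger.warning(
                "arthroscopic set too small for %s/%s; row omitted",
                parameter, variant.name,
            )
    return rows


def _load_study(config: RunConfig) -> StudyData:
    if config.simulate:
        design = StudyDesign(**config.design, seed=config.seed)
        return generate_study(
            design,
            effect=EffectConfig(**config.effect),
            acquisition=AcquisitionConfig(**{
                **config.acquisition,
                "contaminated_locations": frozenset(
                    map(tuple, config.acquisition.get("contaminated_locations", ()))
                ),
            }),
        )
    if not (config.spectra_invitro and config.spectra_arthro and config.references):
        raise ConfigError("simulate=false requires spectra and reference paths")
    design = StudyDesign(**config.design, seed=config.seed)
    return StudyData(
        design=design,
        effect=EffectConfig(**config.effect),
        seed=config.seed,
        references=nio.read_references_csv(config.references),
        invitro=nio.read_spectra_csv(config.spectra_invitro),
        arthro=nio.read_spectra_csv(config.spectra_arthro),
    )


def run_full(config: RunConfig) -> Path:
    """Execute the complete analysis and write the output bundle.

    Outputs in ``config.output_dir``: ``qc.csv``, ``report.csv``,
    ``group_summary.csv``, ``group_comparison.csv``, per-model JSON under
    ``fits/``, and ``manifest.json``. Reruns with the same config and seed
    produce byte-identical reports.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)

    study = _load_study(config)
    logger.info(
        "study: %d in vitro locations, %d arthroscopic locations",
        study.n_invitro_locations, study.n_arthro_locations,
    )

    if len(study.arthro):
        arthro_retained, qc = arthroscopic_qc(
            study.arthro, study.invitro, keep=config.arthro_keep
        )
    else:
        arthro_retained, qc = None, pd.DataFrame()
    qc.to_csv(out / "qc.csv", index=False, float_format="%.6g")

    assignment = split_by_pony(
        study.references,
        config.split_fractions,
        seed=config.seed,
        locations_per_pony=study.design.joints_per_pony
        * study.design.locations_per_joint,
    )

    rows = []
    ss = np.random.SeedSequence([int(config.seed), 0xF17])
    for pi, parameter in enumerate(config.parameters):
        for vi, vname in enumerate(config.variants):
            variant = VARIANTS[vname]
            seed = int(
                np.random.SeedSequence(
                    entropy=ss.entropy, spawn_key=(pi, vi)
                ).generate_state(1)[0]
                % 2**31
            )
            selector, data = fit_parameter_variant(
                study,
                arthro_retained,
                parameter,
                variant,
                assignment,
                selection_params=config.selection,
                random_state=seed,
            )
            rows.extend(
                evaluate_parameter_variant(selector, data, parameter, variant)
            )
            fit_path = out / "fits" / f"{parameter}_{vname}.json"
            fit_path.write_text(
                json.dumps(
                    {
                        "selection": json.loads(selector.result_.to_json()),
                        "fit": json.loads(selector.estimator_.fit_result_.to_json()),
                    },
                    indent=1,
                )
            )

    report = build_report(rows)
    write_report_csv(report, out / "report.csv")
    group_summary(study.references, list(config.parameters)).to_csv(
        out / "group_summary.csv", index=False, float_format="%.6g"
    )
    group_comparison(study.references, list(config.parameters)).to_csv(
        out / "group_comparison.csv", index=False, float_format="%.6g"
    )

    config_dict = config.to_dict()
    manifest = {
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "split": {str(k): v for k, v in sorted(assignment.items())},
        "n_invitro_locations": study.n_invitro_locations,
        "n_arthro_locations": study.n_arthro_locations,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
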