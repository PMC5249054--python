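"""End-to-end orchestration: config, stage composition, results bundle.

The inter-stage contract is CSV (the cohorts are tiny and the tables stay
human-diffable); volumes only enter at the front of the pipeline.  Every
stage logs the parameters it actually applied, and a run is fully
deterministic given its config and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import categorization as cat
from . import morphometry as morph
from . import segmentation as seg
from . import stats as st
from . import synthetic, volume_io

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Pipeline settings; every field has a usable default.

    ``mode`` selects the data source: ``reference`` (bundled cohort, rule
    verification + statistics), ``simulate`` (synthetic cohort), or
    ``volumes`` (segment and measure grayscale volumes under ``input``).
    """

    mode: str = "reference"
    input: str | None = None
    out_dir: str = "mcmorph_results"
    spacing_um: float | None = None
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_voxels: int = 1
    rules: dict = field(default_factory=dict)
    bonferroni_m: int = 4
    alpha: float = 0.05
    include_excluded: bool = False
    n_per_group: int | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("reference", "simulate", "volumes"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ConfigError("threshold_method='fixed' requires fixed_threshold")
        if self.min_voxels < 1:
            raise ConfigError("min_voxels must be >= 1")
        if self.mode == "volumes" and not self.input:
            raise ConfigError("mode='volumes' requires input")

    def classification_rules(self) -> cat.ClassificationRules:
        try:
            return cat.ClassificationRules(**self.rules)
        except TypeError as exc:
            raise ConfigError(f"bad classification rules: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def _classify_records(
    records: list[cat.CohortRecord], rules: cat.ClassificationRules
) -> None:
    for r in records:
        if r.morphometry is not None and not r.morphometry.excluded:
            r.flags = cat.classify_sample(r.morphometry, rules)


def _stats_outputs(
    records: list[cat.CohortRecord], config: PipelineConfig, out: Path
) -> dict[str, Path]:
    paths: dict[str, Path] = {}
    rows = []
    for fld in st.SUMMARY_FIELDS:
        for g, summ in st.group_summary(
            records, fld, include_excluded=config.include_excluded
        ).items():
            rows.append(
                {"field": fld, "group": g, "n": summ.n, "mean": summ.mean, "sd": summ.sd}
            )
    paths["group_summaries"] = _write_csv(pd.DataFrame(rows), out / "group_summaries.csv")

    tests = []
    kw = st.kruskal_wallis_battery(records, include_excluded=config.include_excluded)
    tests.append(kw.assign(p_adjusted=np.nan)[["test", "statistic", "df", "p", "p_adjusted"]])
    chi = st.morphology_tests(records, m=config.bonferroni_m)
    tests.append(chi[["test", "statistic", "df", "p", "p_adjusted"]])
    stats_df = pd.concat(tests, ignore_index=True)
    stats_df["significant"] = stats_df[["p_adjusted", "p"]].bfill(axis=1)["p_adjusted"] < config.alpha
    paths["stats"] = _write_csv(stats_df, out / "stats.csv")

    contingency = []
    for flag in cat.FLAG_NAMES:
        t = cat.presence_table(records, flag)
        contingency.append(
            {"flag": flag, **{f"{g}": f"{t.loc['present', g]}/{t[g].sum()}" for g in cat.GROUPS}}
        )
    paths["contingency"] = _write_csv(pd.DataFrame(contingency), out / "contingency.csv")
    return paths


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the configured pipeline; returns the paths of the results bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    logger.info("pipeline mode=%s seed=%d", config.mode, config.seed)
    rules = config.classification_rules()
    logger.info("classification rules: %s", rules)
    paths: dict[str, Path] = {"config": config.to_yaml(out / "config.yaml")}

    if config.mode == "reference":
        records = synthetic.load_reference_cohort()
        verification = verify_reference_classification(rules)
        paths["classification_verification"] = _write_csv(
            verification, out / "classification_verification.csv"
        )
        paths.update(_stats_outputs(records, config, out))
    elif config.mode == "simulate":
        spec = synthetic.default_cohort_spec(
            n_per_group=config.n_per_group, seed=config.seed
        )
        objects, records = synthetic.make_cohort(spec)
        _classify_records(records, rules)
        paths["objects"] = _write_csv(objects, out / "objects.csv")
        paths["samples"] = _write_csv(
            morph.samples_to_dataframe([r.morphometry for r in records]),
            out / "samples.csv",
        )
        paths["flags"] = _write_csv(
            cat.flags_to_dataframe([r for r in records if r.flags is not None]),
            out / "flags.csv",
        )
        try:
            paths.update(_stats_outputs(records, config, out))
        except ValueError as exc:
            logger.warning("statistics stage skipped: %s", exc)
    else:  # volumes
        records = []
        all_objects = []
        inp = Path(config.input)
        volume_paths = (
            sorted(p for p in inp.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".raw"))
            if inp.is_dir() and not any(inp.glob("*.tif"))
            else [inp]
        )
        samples = []
        for vp in volume_paths:
            volume = volume_io.read_volume(vp, spacing_override=config.spacing_um)
            mask = seg.threshold_volume(
                volume, method=config.threshold_method, fixed_value=config.fixed_threshold
            )
            labeled = seg.filter_objects(
                seg.label_components(mask), min_voxels=config.min_voxels
            )
            objects = morph.measure_objects(labeled)
            df = morph.objects_to_dataframe(objects)
            df.insert(0, "sample_id", vp.stem)
            all_objects.append(df)
            samples.append(morph.aggregate_sample(objects, vp.stem))
        paths["objects"] = _write_csv(
            pd.concat(all_objects, ignore_index=True), out / "objects.csv"
        )
        sample_df = morph.samples_to_dataframe(samples)
        flags = []
        for s in samples:
            if s.n_objects >= 1 and not s.excluded:
                flags.append({"sample_id": s.sample_id, **cat.classify_sample(s, rules).as_dict()})
        paths["samples"] = _write_csv(sample_df, out / "samples.csv")
        paths["flags"] = _write_csv(pd.DataFrame(flags), out / "flags.csv")

    logger.info("pipeline complete; outputs in %s", out)
    return paths


def verify_reference_classification(
    rules: cat.ClassificationRules | None = None,
) -> pd.DataFrame:
    """Re-apply the rule scheme to the bundled cohort and compare flags.

    Verification mode: computed flags are reported next to the recorded
    ones and discordances are flagged, never overwritten.  The documented
    expectations (see ``classification_expectations.csv``) list the known
    discordant samples.
    """
    rules = rules or cat.ClassificationRules()
    rows = []
    for r in synthetic.load_reference_cohort():
        if r.morphometry.excluded:
            continue
        computed = cat.classify_sample(r.morphometry, rules)
        rows.append(
            {
                "sample_id": r.sample_id,
                "group": r.group,
                **{f"recorded_{k}": v for k, v in r.flags.as_dict().items()},
                **{f"computed_{k}": v for k, v in computed.as_dict().items()},
                "concordant": computed == r.flags,
            }
        )
    return pd.DataFrame(rows)
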