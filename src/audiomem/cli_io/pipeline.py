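"""End-to-end pipeline stages: simulate, score, analyze.

The analyze stage mirrors the study's cascade: a multivariate
distance-based permutation test over the three indices with Age as a
covariate, follow-up mixed-design permutation ANOVAs per index (run
only when the multivariate test flags a design term, with Age dropped
when all its terms are non-significant), and Bonferroni-corrected
permutation t-tests between groups within each difficulty level.
"""

from __future__ import annotations

import logging
import math
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from ..agents import generate_cohort
from ..indices import (
    IncompleteSessionError,
    compute_audio_anchor,
    compute_number_of_attempts,
    compute_score,
)
from ..permstats import (
    StatResult,
    bonferroni,
    dist_perm_manova,
    perm_anova,
    perm_t_test,
    validate_model_table,
)
from .config import PipelineConfig
from .serialization import read_log, write_log, write_table

logger = logging.getLogger("audiomem")

INDEX_COLUMNS = ("score", "number_of_attempts", "audio_anchor")
MANOVA_TERMS = (
    "group",
    "difficulty",
    "age",
    "group:difficulty",
    "group:age",
    "difficulty:age",
    "group:age:difficulty",
)
AGE_TERMS = tuple(t for t in MANOVA_TERMS if "age" in t)
DESIGN_TERMS = tuple(t for t in MANOVA_TERMS if "age" not in t)


def cmd_simulate(config: PipelineConfig) -> pd.DataFrame:
    """Simulate the cohort, writing the index table, logs and a manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "simulating cohort: %d per group, master_seed=%d",
        config.cohort.n_per_group,
        config.cohort.master_seed,
    )
    table, logs = generate_cohort(config.cohort)
    write_table(table, out / "cohort.csv")
    log_dir = out / "logs"
    log_dir.mkdir(exist_ok=True)
    for log in logs:
        write_log(log, log_dir / f"{log.subject_id}_{log.condition.name}.csv")
    manifest = {
        "master_seed": config.cohort.master_seed,
        "n_per_group": config.cohort.n_per_group,
        "conditions": list(config.cohort.conditions),
        "groups": sorted(config.cohort.group_params),
        "n_sessions": len(logs),
        "seed_scheme": "numpy SeedSequence(master_seed).spawn, fixed order",
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    logger.info("wrote %d sessions to %s", len(logs), out)
    return table


def cmd_score(
    log_paths: Sequence[Union[str, Path]], *, partial: bool = True
) -> pd.DataFrame:
    """Score each session log file into one index row."""
    rows = []
    for path in log_paths:
        log = read_log(path)
        log.validate()
        score = compute_score(log, validate=False)
        anchor = compute_audio_anchor(log, validate=False)
        try:
            with warnings.catch_warnings():
                if partial:
                    warnings.simplefilter("always")
                noa = compute_number_of_attempts(
                    log, validate=False, partial=partial
                )
        except IncompleteSessionError:
            if not partial:
                raise
            noa = math.nan
            logger.warning("partial session with no matched pairs: %s", path)
        rows.append(
            {
                "subject_id": log.subject_id,
                "group": log.group,
                "age": log.age,
                "condition": log.condition.name,
                "score": score,
                "number_of_attempts": noa,
                "audio_anchor": anchor,
                "n_attempts_total": len(log.attempts),
            }
        )
    return pd.DataFrame(rows)


def _as_model_table(index_table: pd.DataFrame) -> pd.DataFrame:
    table = index_table.rename(columns={"condition": "difficulty"}).copy()
    required = {"subject_id", "group", "difficulty", "age", *INDEX_COLUMNS}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"index table missing columns: {sorted(missing)}")
    validate_model_table(table, list(INDEX_COLUMNS))
    return table


def _result_row(stage: str, response: str, res: StatResult, **extra) -> dict:
    row = {
        "stage": stage,
        "response": response,
        "term": res.term,
        "statistic": res.statistic,
        "df1": res.df[0] if res.df else None,
        "df2": res.df[1] if res.df else None,
        "p_perm": res.p_perm,
        "n_perm": res.n_perm,
        "effect_size": res.effect_size,
        "effect_size_kind": res.effect_size_kind,
        "exhaustive": res.exhaustive,
        "seed": res.seed,
    }
    row.update(extra)
    return row


def cmd_analyze(
    index_table: pd.DataFrame,
    config: PipelineConfig,
    out_dir: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Run the full inference cascade over a cohort index table."""
    table = _as_model_table(index_table)
    stats = config.stats
    alpha = stats.alpha
    rows: list[dict] = []

    logger.info("multivariate distance-based test (%d permutations)", stats.n_perm)
    manova = dist_perm_manova(
        table,
        list(INDEX_COLUMNS),
        terms=MANOVA_TERMS,
        distance=stats.distance,
        n_perm=stats.n_perm,
        seed=stats.seed,
        strata="subject_id" if stats.strata else None,
    )
    for term, res in manova.items():
        rows.append(
            _result_row(
                "multivariate", "all_indices", res,
                significant=res.p_perm < alpha,
            )
        )

    age_significant = any(manova[t].p_perm < alpha for t in AGE_TERMS)
    if age_significant:
        logger.warning(
            "age terms significant at alpha=%.3g; follow-ups still use the "
            "group x difficulty decomposition — interpret with care", alpha
        )
    else:
        logger.info("no age effect at alpha=%.3g; age dropped from follow-ups",
                    alpha)

    run_followups = any(manova[t].p_perm < alpha for t in DESIGN_TERMS)
    posthoc_jobs: list[tuple[str, str]] = []
    if run_followups:
        for response in INDEX_COLUMNS:
            logger.info("follow-up permutation ANOVA: %s", response)
            anova = perm_anova(
                table,
                response,
                n_perm=stats.n_perm,
                seed=stats.seed,
                scheme=stats.scheme,
            )
            for term, res in anova.items():
                rows.append(
                    _result_row(
                        "anova", response, res,
                        significant=res.p_perm < alpha,
                    )
                )
            if (
                anova["group"].p_perm < alpha
                or anova["group:difficulty"].p_perm < alpha
            ):
                for level in sorted(table["difficulty"].unique()):
                    posthoc_jobs.append((response, level))
    else:
        logger.info("no multivariate design effect; follow-ups skipped")

    if posthoc_jobs:
        groups = sorted(table["group"].unique())
        raw_rows = []
        for response, level in posthoc_jobs:
            sub = table[table["difficulty"] == level]
            x = sub.loc[sub["group"] == groups[0], response].to_numpy()
            y = sub.loc[sub["group"] == groups[1], response].to_numpy()
            res = perm_t_test(x, y, n_perm=stats.n_perm, seed=stats.seed)
            raw_rows.append((response, level, res))
        corrected = bonferroni([r.p_perm for _, _, r in raw_rows])
        for (response, level, res), p_bonf in zip(raw_rows, corrected):
            rows.append(
                _result_row(
                    "posthoc_t", response, res,
                    term=f"{groups[0]} vs {groups[1]} @ {level}",
                    p_bonferroni=p_bonf,
                    significant=p_bonf < alpha,
                )
            )

    report = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(report, out / "results.csv")
        with open(out / "results.txt", "w") as fh:
            fh.write(format_report(report))
    return report


def format_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of the results table."""
    lines = ["permutation analysis report", "=" * 27, ""]
    for stage, title in (
        ("multivariate", "Multivariate distance-based test"),
        ("anova", "Follow-up permutation ANOVAs"),
        ("posthoc_t", "Post hoc permutation t-tests (Bonferroni)"),
    ):
        sub = report[report["stage"] == stage]
        if sub.empty:
            continue
        lines.append(title)
        lines.append("-" * len(title))
        for _, r in sub.iterrows():
            extra = ""
            if stage == "posthoc_t" and "p_bonferroni" in r:
                extra = f", p_bonf={r['p_bonferroni']:.4g}"
            star = " *" if r.get("significant") else ""
            lines.append(
                f"  {r['response']:>20s} | {r['term']:<28s} "
                f"stat={r['statistic']:8.4f}  p={r['p_perm']:.4g}{extra}  "
                f"{r['effect_size_kind']}={r['effect_size']:.3f}"
                f" (n_perm={int(r['n_perm'])}){star}"
            )
        lines.append("")
    return "\n".join(lines)
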