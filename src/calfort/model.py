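"""Model/results interface for the fortification simulation.

:class:`FlourFortification` bundles the survey inputs (recall records,
subjects, flour map, reference table); :meth:`FlourFortification.fit` runs
the scenario at a chosen fortification level and returns a
:class:`FortificationResults` carrying the per-group estimates, the
pre/post usual-intake distributions, warnings, and rendering/saving
helpers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .fortification import (
    DEFAULT_LEVEL_MG_PER_100G,
    DEFAULT_MIN_N,
    FortificationSpec,
    ScenarioResult,
    ScenarioRun,
    run_scenario,
)
from .recall_data import (
    FlourMap,
    RecallRecord,
    Subject,
    read_recalls,
    read_subjects,
)
from .reference_values import DRITable
from .usual_intake import UsualIntakeDistribution, VarianceRatioSpec

__all__ = ["FlourFortification", "FortificationResults"]


class FlourFortification:
    """A fortification-scenario model over one dietary survey.

    Parameters
    ----------
    records, subjects, flour_map
        The survey: per-item recall records, participant roster with
        survey weights, and the food-to-flour-fraction map.
    dri_table
        EAR/UL reference table; defaults to the shipped calcium table.
    """

    def __init__(
        self,
        records: Sequence[RecallRecord],
        subjects: Sequence[Subject],
        flour_map: FlourMap,
        dri_table: DRITable | None = None,
    ):
        self.records = list(records)
        self.subjects = list(subjects)
        self.flour_map = flour_map
        self.dri_table = dri_table or DRITable.default()

    @classmethod
    def from_files(
        cls,
        recalls_path: str | Path,
        subjects_path: str | Path,
        flour_map_path: str | Path,
        dri_table_path: str | Path | None = None,
    ) -> "FlourFortification":
        """Build the model from the three delimited input files."""
        return cls(
            records=read_recalls(recalls_path),
            subjects=read_subjects(subjects_path),
            flour_map=FlourMap.from_csv(flour_map_path),
            dri_table=(
                DRITable.from_csv(dri_table_path) if dri_table_path else None
            ),
        )

    def fit(
        self,
        level_mg_per_100g: float = DEFAULT_LEVEL_MG_PER_100G,
        variance_mode: str = "internal",
        variance_ratio: float | None = None,
        *,
        flour_types: Iterable[str] | None = None,
        transformation: str = "log",
        bias_correction: bool = True,
        min_n: int = DEFAULT_MIN_N,
    ) -> "FortificationResults":
        """Run the scenario and return the fitted results.

        ``variance_mode='internal'`` estimates within/between variance from
        repeat recalls; ``'external'`` uses ``variance_ratio`` (needed when
        every subject has a single recall day).
        """
        run = run_scenario(
            self.records,
            self.subjects,
            self.flour_map,
            self.dri_table,
            FortificationSpec(level_mg_per_100g=level_mg_per_100g),
            VarianceRatioSpec(mode=variance_mode, ratio=variance_ratio),
            flour_types=flour_types,
            transformation=transformation,
            bias_correction=bias_correction,
            min_n=min_n,
        )
        return FortificationResults(self, run)


@dataclass
class FortificationResults:
    """Fitted scenario results, one row per analysed life-stage group."""

    model: FlourFortification
    run: ScenarioRun

    @property
    def results(self) -> list[ScenarioResult]:
        return self.run.results

    @property
    def warnings(self) -> list[str]:
        return self.run.warnings

    def frame(self) -> pd.DataFrame:
        """Results as a DataFrame in the published-table column order."""
        return self.run.frame()

    def distributions(
        self, label: str
    ) -> tuple[UsualIntakeDistribution, UsualIntakeDistribution]:
        """(pre, post) usual-intake distributions for one group label."""
        return self.run.distributions[label]

    def summary(self) -> str:
        """Plain-text per-group table (percentages and mg to 1 decimal)."""
        level = self.run.config["level_mg_per_100g"]
        header = (
            f"Flour fortification scenario: {level:g} mg calcium per 100 g flour\n"
            f"{'group':<28}{'n':>6}{'EAR':>6}{'UL':>6}"
            f"{'%flour':>8}{'flour_g':>9}"
            f"{'pre_mean':>10}{'pre<EAR%':>10}{'pre>UL%':>9}"
            f"{'post_mean':>11}{'post<EAR%':>11}{'post>UL%':>10}"
            f"{'gap_mg':>8}"
        )
        lines = [header, "-" * len(header.splitlines()[-1])]
        for r in self.results:
            lines.append(
                f"{r.group.label:<28}{r.n:>6}{r.entry.ear_mg:>6.0f}"
                f"{r.entry.ul_mg:>6.0f}"
                f"{r.flour.pct_consuming:>8.1f}{r.flour.mean_flour_g:>9.1f}"
                f"{r.pre.mean_mg:>10.1f}{r.pre.pct_below_ear:>10.1f}"
                f"{r.pre.pct_above_ul:>9.1f}"
                f"{r.post.mean_mg:>11.1f}{r.post.pct_below_ear:>11.1f}"
                f"{r.post.pct_above_ul:>10.1f}"
                f"{r.gap.initial_gap_mg:>8.1f}"
            )
        return "\n".join(lines)

    def plot_density(self, label: str, ax=None):
        """Overlayed pre/post usual-intake density for one group."""
        from .plotting import plot_pre_post_density

        pre, post = self.distributions(label)
        result = next(r for r in self.results if r.group.label == label)
        return plot_pre_post_density(pre, post, result.entry, label, ax=ax)

    def save(
        self, outdir: str | Path, *, plots: bool = False, seed: int | None = None
    ) -> None:
        """Write results CSV, per-group distribution CSVs, metadata JSON,
        and (optionally) density plots into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.frame().to_csv(outdir / "results.csv", index=False)
        dist_dir = outdir / "distributions"
        dist_dir.mkdir(exist_ok=True)
        for label, (pre, post) in self.run.distributions.items():
            safe = label.replace(" ", "").replace("<=", "le").replace(">=", "ge")
            for tag, dist in (("pre", pre), ("post", post)):
                pd.DataFrame(
                    {
                        "subject_id": dist.subject_ids,
                        "usual_mg": dist.values_mg,
                        "weight": dist.weights,
                    }
                ).to_csv(dist_dir / f"{safe}_{tag}.csv", index=False)
        meta = {
            "version": __version__,
            "config": self.run.config,
            "seed": seed,
            "n_groups": len(self.results),
            "warnings": self.run.warnings,
        }
        (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
        if plots:
            from .plotting import save_density_plots

            save_density_plots(self, outdir / "plots")
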