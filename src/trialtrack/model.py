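"""Model-style front end: build a tracker from data, fit, inspect results.

``TrialTracker`` holds the inputs (trial records, evidence corpus,
institution, tracking configuration); ``fit`` runs the deterministic
pipeline at a snapshot date and returns a ``TrackingResults`` object
carrying the rate table, search yields, reliability summary and the
ten-variable manifest, with a formatted ``summary()`` and plotting helpers.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .benchmark import BenchmarkReport, run_tracking, sensitivity_grid
from .config import TrackingConfig
from .registry_io import (
    PublicationEvidence,
    TrialRecord,
    read_publication_corpus,
    read_registry_records,
)

__all__ = ["TrialTracker", "TrackingResults"]


class TrialTracker:
    """Publication-tracking model for one institution's registered trials."""

    def __init__(
        self,
        records: Sequence[TrialRecord],
        corpus: Sequence[PublicationEvidence],
        institution: str,
        config: Optional[TrackingConfig] = None,
        institution_patterns: Optional[Sequence[str]] = None,
    ):
        self.records = list(records)
        self.corpus = list(corpus)
        self.institution = institution
        self.config = config or TrackingConfig()
        self.institution_patterns = (
            list(institution_patterns) if institution_patterns else [institution]
        )

    @classmethod
    def from_files(
        cls,
        registry_path: Union[str, Path],
        corpus_path: Union[str, Path],
        institution: str,
        dialect: str = "flat_csv",
        config: Optional[TrackingConfig] = None,
        institution_patterns: Optional[Sequence[str]] = None,
    ) -> "TrialTracker":
        records, record_issues = read_registry_records(registry_path, dialect)
        corpus, corpus_issues = read_publication_corpus(corpus_path)
        model = cls(records, corpus, institution, config, institution_patterns)
        model.record_issues = record_issues
        model.corpus_issues = corpus_issues
        return model

    def fit(self, snapshot_date: dt.date) -> "TrackingResults":
        report = run_tracking(
            self.records,
            self.corpus,
            self.institution,
            self.config,
            snapshot_date,
            self.institution_patterns,
        )
        return TrackingResults(self, report)

    def fit_grid(
        self, configs: Sequence[TrackingConfig], snapshot_date: dt.date
    ) -> pd.DataFrame:
        """Sensitivity grid: one full tracking run per configuration variant."""
        return sensitivity_grid(
            self.records,
            self.corpus,
            self.institution,
            configs,
            snapshot_date,
            self.institution_patterns,
        )


class TrackingResults:
    """Fitted tracking results with accounting tables and a text summary."""

    def __init__(self, model: TrialTracker, report: BenchmarkReport):
        self.model = model
        self.report = report

    @property
    def manifest(self) -> Dict[str, object]:
        return self.report.manifest

    @property
    def rate_table(self) -> pd.DataFrame:
        return self.report.rate_frame()

    @property
    def yield_table(self) -> pd.DataFrame:
        return self.report.yields

    @property
    def reliability(self) -> Optional[Dict[str, object]]:
        return self.report.reliability

    @property
    def flow(self) -> Dict[str, object]:
        return self.report.flow

    def save(self, outdir: Union[str, Path]) -> None:
        self.report.write(outdir)

    def summary(self) -> str:
        r = self.report
        width = 72
        lines = [
            "Clinical Study Publication Tracking".center(width),
            "=" * width,
            f"Institution: {r.institution}",
            f"Snapshot: {r.snapshot_date.isoformat()}    Config hash: {r.manifest['config_hash']}",
            f"Sample flow: {r.flow['input']} records -> {r.flow['included']} tracked"
            + (f"  (excluded: {r.flow['excluded']})" if r.flow["excluded"] else ""),
            "-" * width,
            "Publication rates",
            f"{'reference':<14}{'window':>9}{'stratum':<20}{'num':>6}{'den':>6}{'cens':>6}{'rate':>9}",
        ]
        for cell in r.rates:
            window = "all-time" if cell.window_months is None else f"{cell.window_months}m"
            rate = "undef" if cell.rate is None else f"{cell.rate:.3f}"
            lines.append(
                f"{cell.reference:<14}{window:>9}  {cell.stratum:<18}"
                f"{cell.numerator:>6}{cell.denominator:>6}{cell.censored:>6}{rate:>9}"
            )
        lines.append("-" * width)
        lines.append("Search yield by source (first found)")
        for _, row in r.yields.iterrows():
            lines.append(
                f"  {row['source']:<22}{row['n_new']:>6} new   cumulative "
                f"{row['cumulative_proportion']:.3f}"
            )
        if r.reliability is not None:
            lines.append("-" * width)
            raters = r.reliability.get("raters")
            lines.append(f"Inter-rater reliability (manual search, raters {raters})")
            for cat, prop in r.reliability["proportions"].items():
                lines.append(f"  {cat:<26}{prop:.3f}")
            lines.append(f"  date conflicts: {r.reliability['date_conflicts']}")
        lines.append("=" * width)
        return "\n".join(lines)

    def plot_rates(self, ax=None, stratum: str = "all"):
        """Bar chart of publication rates by window for one stratum."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        cells = [c for c in self.report.rates if c.stratum == stratum and c.rate is not None]
        labels = ["all-time" if c.window_months is None else f"{c.window_months}m" for c in cells]
        ax.bar(range(len(cells)), [c.rate for c in cells], color="#4878a8")
        ax.set_xticks(range(len(cells)), labels)
        ax.set_ylim(0, 1)
        ax.set_ylabel("proportion published")
        ax.set_title(f"Publication rates ({stratum}, ref={self.model.config.completion.reference.value})")
        return ax

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<TrackingResults institution={self.report.institution!r} "
            f"n={self.report.flow['included']} hash={self.report.manifest['config_hash']}>"
        )
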