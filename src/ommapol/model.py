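"""Model/Results interface to the patch-alignment analysis.

`PatchAlignmentModel` holds the observed data (an eyeshine stack plus ROI
grid, or extracted intensity series directly); `.fit()` estimates every
ommatidium's principal axis and returns a `PatchAlignmentResults`
carrying the estimates, their quality diagnostics, the lattice
classification, and a text `summary()`.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from . import alignment, hexarray, photometry
from .photometry import HexROIGrid, IntensitySeries
from .synthgen import EyeshineStack, SigmaField

Coord = tuple[int, int]


class PatchAlignmentModel:
    """Per-ommatidium periodic-intensity model of one eye patch.

    Each ommatidium's depolarized eyeshine over roll angle is modelled
    as ``a + b * sin^2(2 * (theta - Sigma))``; fitting the patch yields
    a Sigma field and the ED/PD classification built on it.

    Parameters
    ----------
    series : mapping (q, r) -> IntensitySeries
        Extracted intensity-versus-theta series, one per ommatidium.
    """

    def __init__(self, series: Mapping[Coord, IntensitySeries]):
        if not series:
            raise ValueError("no intensity series supplied")
        self.series = dict(series)

    @classmethod
    def from_stack(
        cls,
        stack: EyeshineStack,
        grid: HexROIGrid,
        channel: str = "mono",
    ) -> "PatchAlignmentModel":
        """Build the model by ROI photometry of a registered stack."""
        return cls(photometry.extract_intensity_series(stack, grid, channel))

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "PatchAlignmentModel":
        """Build from a long-format series table
        (patch_id, q, r, channel, theta_deg, intensity)."""
        return cls(photometry.series_from_frame(frame))

    def fit(
        self,
        qc_threshold: float = alignment.DEFAULT_QC_THRESHOLD,
        ed_tol: float = hexarray.DEFAULT_ED_TOL,
        min_len: int = hexarray.DEFAULT_MIN_CHAIN,
        pd_threshold: float = hexarray.DEFAULT_PD_THRESHOLD,
    ) -> "PatchAlignmentResults":
        field, table = alignment.estimate_patch(self.series, qc_threshold)
        return PatchAlignmentResults(
            model=self,
            field=field,
            estimates=table,
            qc_threshold=qc_threshold,
            ed_tol=ed_tol,
            min_len=min_len,
            pd_threshold=pd_threshold,
        )


class PatchAlignmentResults:
    """Fitted principal axes and lattice classification of a patch."""

    def __init__(self, model, field: SigmaField, estimates: pd.DataFrame,
                 qc_threshold: float, ed_tol: float, min_len: int,
                 pd_threshold: float):
        self.model = model
        self.field = field
        self.estimates = estimates
        self.qc_threshold = qc_threshold
        self.ed_tol = ed_tol
        self.min_len = min_len
        self.pd_threshold = pd_threshold
        self._pairs = None
        self._chains = None
        self._metrics = None

    @property
    def sigma(self) -> pd.Series:
        """Fitted Sigma (deg) of QC-passing ommatidia, indexed by (q, r)."""
        ok = self.estimates[self.estimates.qc_pass]
        return pd.Series(
            ok.sigma_deg.to_numpy(),
            index=pd.MultiIndex.from_arrays([ok.q, ok.r], names=["q", "r"]),
            name="sigma_deg",
        )

    @property
    def pairs(self):
        if self._pairs is None:
            self._pairs = hexarray.adjacent_pairs(
                self.field, pd_threshold=self.pd_threshold
            )
        return self._pairs

    @property
    def chains(self):
        if self._chains is None:
            self._chains = hexarray.find_ed_chains(
                self.field, ed_tol=self.ed_tol, min_len=self.min_len
            )
        return self._chains

    @property
    def metrics(self) -> hexarray.PatchMetrics:
        if self._metrics is None:
            self._metrics = hexarray.patch_metrics(
                self.field,
                ed_tol=self.ed_tol,
                min_len=self.min_len,
                pd_threshold=self.pd_threshold,
            )
        return self._metrics

    def delta_sigma_distribution(self) -> dict:
        return hexarray.delta_sigma_distribution(
            self.pairs, pd_threshold=self.pd_threshold
        )

    def summary(self) -> str:
        """Readable report of the fit and classification."""
        est = self.estimates
        m = self.metrics
        d = m.delta_sigma_summary
        lines = [
            "Patch alignment fit",
            "=" * 51,
            f"{'Ommatidia (series)':<34}{len(est):>17d}",
            f"{'Passing QC (mod >= %.2f)' % self.qc_threshold:<34}"
            f"{int(est.qc_pass.sum()):>17d}",
            f"{'Median modulation depth':<34}"
            f"{est.modulation.median():>17.3f}",
            f"{'Interior ommatidia':<34}{m.n_interior:>17d}",
            f"{'Adjacent pairs (>=1 interior)':<34}{m.n_pairs:>17d}",
            "-" * 51,
            f"{'%% ED (chains, +/-%g deg)' % self.ed_tol:<34}"
            f"{m.pct_ed:>16.1f}%",
            f"{'%% PD (delta >= %g deg)' % self.pd_threshold:<34}"
            f"{m.pct_pd:>16.1f}%",
            f"{'% ED only':<34}{m.pct_ed_only:>16.1f}%",
            f"{'% PD only':<34}{m.pct_pd_only:>16.1f}%",
            "-" * 51,
            "Adjacent-pair axial differences:",
            f"{'  exactly aligned':<34}{100 * d['exact']:>16.1f}%",
            f"{'  within +/-5 deg':<34}{100 * d['within_5']:>16.1f}%",
            f"{'  >= 15 deg':<34}{100 * d['ge_15']:>16.1f}%",
            f"{'  >= 20 deg':<34}{100 * d['ge_20']:>16.1f}%",
            "=" * 51,
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<PatchAlignmentResults: {len(self.estimates)} ommatidia, "
            f"{int(self.estimates.qc_pass.sum())} passing QC>"
        )
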