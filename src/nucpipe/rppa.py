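"""Reverse-phase protein array (RPPA) quantification.

Lysates are spotted as a doubling dilution series (typically four steps,
factors 1, 2, 4, 8) in technical triplicate and probed with one validated
antibody per slide. Quantification proceeds:

1. per dilution step, the median over technical spots;
2. a least-squares line through log2(median intensity) versus
   log2(dilution factor); the relative fluorescence intensity (RFI) is the
   fitted intensity at factor 1 (the back-transformed intercept), with the
   slope and r² retained as fit diagnostics — an ideal doubling series has
   slope −1, and a series with r² < 0.2 is flagged as non-dilutional;
3. loading correction: each sample's RFI divided by the same sample's RFI
   from a total-protein stain;
4. enrichment: per biological replicate, the loading-corrected RFI of the
   experimental line divided by that of its matched control line, then the
   mean over replicates (log2 values exported for heat maps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DilutionSeries",
    "RFIRecord",
    "fit_dilution_series",
    "rfi_frame",
    "normalise_loading",
    "enrichment_table",
    "EnrichmentResult",
    "heatmap_matrix",
    "read_rppa_csv",
    "series_to_frame",
]

R2_FLAG_THRESHOLD = 0.2


@dataclass
class DilutionSeries:
    """Spot intensities for one antibody × sample dilution series."""

    antibody: str
    sample_id: str
    intensities: np.ndarray  # (n_steps, n_spots), non-negative
    dilution_factors: tuple = (1, 2, 4, 8)

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        factors = tuple(float(f) for f in self.dilution_factors)
        if arr.shape[0] != len(factors):
            raise ValueError(
                f"{arr.shape[0]} intensity rows but {len(factors)} dilution factors"
            )
        if len(factors) < 2:
            raise ValueError("a dilution series needs at least 2 steps")
        if arr.shape[1] < 1:
            raise ValueError("each dilution step needs at least one spot")
        if np.any(arr < 0):
            raise ValueError("spot intensities must be non-negative")
        ratios = np.diff(factors) / np.asarray(factors[:-1])
        if np.any(np.asarray(factors) <= 0) or np.any(np.diff(factors) <= 0):
            raise ValueError("dilution factors must be positive and increasing")
        if not np.allclose(ratios, 1.0):
            raise ValueError(f"expected a doubling series, got factors {factors}")
        self.intensities = arr
        self.dilution_factors = factors


@dataclass
class RFIRecord:
    """Fitted relative fluorescence intensity for one antibody × sample."""

    antibody: str
    sample_id: str
    rfi: float
    fit_slope: float
    fit_r2: float
    flagged: bool


def fit_dilution_series(series: DilutionSeries) -> RFIRecord:
    """Fit the dilution line and report the RFI at the undiluted reference.

    Step medians that are not strictly positive are dropped (log-space fit);
    at least two positive medians must remain. A constant series fits with
    slope 0 and is flagged (r² is taken as 0 when the medians have no
    spread, which trips the non-dilutional flag).
    """
    medians = np.median(series.intensities, axis=1)
    keep = medians > 0
    if keep.sum() < 2:
        raise ValueError(
            f"{series.antibody}/{series.sample_id}: fewer than two dilution "
            "steps with positive median intensity"
        )
    if not keep.all():
        logger.warning(
            "%s/%s: dropping %d non-positive step median(s)",
            series.antibody,
            series.sample_id,
            int((~keep).sum()),
        )
    x = np.log2(np.asarray(series.dilution_factors)[keep])
    y = np.log2(medians[keep])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    flagged = r2 < R2_FLAG_THRESHOLD
    if flagged:
        logger.warning(
            "%s/%s: non-dilutional series (r2=%.3f)",
            series.antibody,
            series.sample_id,
            r2,
        )
    return RFIRecord(
        antibody=series.antibody,
        sample_id=series.sample_id,
        rfi=float(2.0**intercept),
        fit_slope=float(slope),
        fit_r2=r2,
        flagged=flagged,
    )


def rfi_frame(records) -> pd.DataFrame:
    """RFI records as a table (antibody, sample_id, rfi, diagnostics)."""
    return pd.DataFrame(
        [
            {
                "antibody": r.antibody,
                "sample_id": r.sample_id,
                "rfi": r.rfi,
                "fit_slope": r.fit_slope,
                "fit_r2": r.fit_r2,
                "flagged": r.flagged,
            }
            for r in records
        ],
        columns=["antibody", "sample_id", "rfi", "fit_slope", "fit_r2", "flagged"],
    )


def normalise_loading(
    rfi: pd.DataFrame, total_protein: pd.DataFrame
) -> pd.DataFrame:
    """Divide each sample's RFI by that sample's total-protein RFI.

    ``total_protein`` holds one row per sample (e.g. from a Fast Green
    stained slide). A sample with no, or zero, total-protein readout is an
    error — loading correction cannot be skipped silently.
    """
    totals = total_protein.set_index("sample_id")["rfi"]
    if totals.index.duplicated().any():
        raise ValueError("duplicate total-protein rows for a sample")
    out = rfi.copy()
    missing = sorted(set(out["sample_id"]) - set(totals.index))
    if missing:
        raise ValueError(f"samples without total-protein RFI: {missing}")
    denom = out["sample_id"].map(totals)
    if (denom <= 0).any():
        bad = sorted(out.loc[denom <= 0, "sample_id"].unique())
        raise ValueError(f"non-positive total-protein RFI for samples: {bad}")
    out["normalised_rfi"] = out["rfi"] / denom
    return out


@dataclass
class EnrichmentResult:
    """Per-replicate enrichment ratios plus the replicate-mean summary."""

    line: str
    per_replicate: pd.DataFrame  # antibody, replicate, exp/ctrl sample ids, enrichment
    summary: pd.DataFrame  # antibody, n_replicates, mean_enrichment, log2_mean_enrichment


def enrichment_table(
    experimental: pd.DataFrame,
    control: pd.DataFrame,
    pairing: list[tuple[str, str]],
    line: str = "experimental",
) -> EnrichmentResult:
    """Enrichment of an experimental line over its matched control line.

    ``pairing`` lists (experimental_sample_id, control_sample_id) per
    biological replicate; every pair must exist in both tables for every
    antibody. Input frames must carry ``normalised_rfi`` (loading-corrected).
    """
    for name, df in (("experimental", experimental), ("control", control)):
        if "normalised_rfi" not in df.columns:
            raise ValueError(f"{name} table lacks normalised_rfi; run normalise_loading")
    exp_ix = experimental.set_index(["antibody", "sample_id"])["normalised_rfi"]
    ctl_ix = control.set_index(["antibody", "sample_id"])["normalised_rfi"]
    antibodies = sorted(set(experimental["antibody"]))
    rows = []
    for ab in antibodies:
        for rep, (exp_s, ctl_s) in enumerate(pairing, start=1):
            try:
                e = float(exp_ix[(ab, exp_s)])
                c = float(ctl_ix[(ab, ctl_s)])
            except KeyError as exc:
                raise ValueError(
                    f"unpaired replicate: antibody {ab!r} missing sample "
                    f"{exc.args[0]!r}"
                ) from exc
            if c <= 0:
                raise ValueError(f"control RFI <= 0 for {ab!r}/{ctl_s!r}")
            rows.append(
                {
                    "antibody": ab,
                    "replicate": rep,
                    "experimental_sample": exp_s,
                    "control_sample": ctl_s,
                    "enrichment": e / c,
                }
            )
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby("antibody", as_index=False)
        .agg(
            n_replicates=("enrichment", "size"),
            mean_enrichment=("enrichment", "mean"),
        )
        .assign(log2_mean_enrichment=lambda d: np.log2(d["mean_enrichment"]))
    )
    return EnrichmentResult(line=line, per_replicate=per_rep, summary=summary)


def heatmap_matrix(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Antibody × line matrix of log2 mean enrichment, for heat-map export."""
    frames = []
    for res in results:
        frames.append(
            res.summary[["antibody", "log2_mean_enrichment"]]
            .set_index("antibody")
            .rename(columns={"log2_mean_enrichment": res.line})
        )
    return pd.concat(frames, axis=1).sort_index()


# ---------------------------------------------------------------------------
# CSV interchange (long format: antibody, sample_id, dilution_factor, spot, intensity)


def series_to_frame(series_list) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for i, f in enumerate(s.dilution_factors):
            for j in range(s.intensities.shape[1]):
                rows.append(
                    {
                        "antibody": s.antibody,
                        "sample_id": s.sample_id,
                        "dilution_factor": f,
                        "spot": j + 1,
                        "intensity": s.intensities[i, j],
                    }
                )
    return pd.DataFrame(
        rows, columns=["antibody", "sample_id", "dilution_factor", "spot", "intensity"]
    )


def read_rppa_csv(path) -> list[DilutionSeries]:
    df = pd.read_csv(path)
    needed = {"antibody", "sample_id", "dilution_factor", "spot", "intensity"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"RPPA CSV missing columns: {sorted(missing)}")
    out = []
    for (ab, sample), grp in df.groupby(["antibody", "sample_id"], sort=True):
        piv = grp.pivot_table(
            index="dilution_factor", columns="spot", values="intensity"
        ).sort_index()
        out.append(
            DilutionSeries(
                antibody=str(ab),
                sample_id=str(sample),
                intensities=piv.to_numpy(),
                dilution_factors=tuple(piv.index),
            )
        )
    return out
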