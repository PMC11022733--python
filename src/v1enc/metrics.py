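"""Evaluation statistics for repeated-stimulus test sets.

Three per-neuron quantities are computed from a table of responses ``r_ij``
(image i, repeat j) and predictions ``o_i``:

* **Correlation to Average** (R̄): Pearson correlation between the predictions
  and the repeat-averaged responses across images.
* **FEV** — fraction of explainable variance: the share of a neuron's total
  response variance that is stimulus-driven, ``(Var[r] - sigma_eps^2) /
  Var[r]`` where ``sigma_eps^2`` is the mean within-image (repeat-to-repeat)
  variance.
* **FEVE** — fraction of explainable variance explained:
  ``1 - (MSE - sigma_eps^2) / (Var[r] - sigma_eps^2)`` with the mean squared
  error taken over all trials.

All variances are population (divide-by-N) so that noiseless repeats give
exactly FEV = FEVE = 1; a ``ddof`` switch allows the sample convention for
comparison. Neurons whose statistic is undefined (zero variance, non-positive
explainable variance) are reported as NaN and excluded from aggregates — they
are never coerced to 0, since low-explainable-variance neurons can take large
negative FEVE values that would bias a population mean. The aggregate FEVE is
restricted to neurons whose FEV exceeds a threshold (default 15%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FEV_THRESHOLD = 0.15


@dataclass
class RepeatTable:
    """Responses grouped by stimulus plus one prediction per stimulus.

    ``responses`` is a list over images of (J_i, m) arrays (J_i >= 2 repeats
    for FEV/FEVE); ``predictions`` is (I, m), in the same standardized units.
    """

    responses: list[np.ndarray]
    predictions: np.ndarray

    def __post_init__(self) -> None:
        self.responses = [np.asarray(r, dtype=np.float64) for r in self.responses]
        self.predictions = np.asarray(self.predictions, dtype=np.float64)
        if self.predictions.ndim != 2 or len(self.responses) != self.predictions.shape[0]:
            raise ValueError("predictions must be (n_images, m) matching responses")
        m = self.predictions.shape[1]
        for i, r in enumerate(self.responses):
            if r.ndim != 2 or r.shape[1] != m:
                raise ValueError(f"image {i}: responses must be (J_i, {m}), got {r.shape}")

    @property
    def n_images(self) -> int:
        return len(self.responses)

    @property
    def n_neurons(self) -> int:
        return self.predictions.shape[1]

    def repeat_means(self) -> np.ndarray:
        """(I, m) mean response per image."""
        return np.stack([r.mean(axis=0) for r in self.responses])


@dataclass
class MetricReport:
    r_bar: np.ndarray          # per-neuron correlation to average (NaN when undefined)
    fev: np.ndarray            # per-neuron fraction of explainable variance
    feve: np.ndarray           # per-neuron FEVE
    mean_r_bar: float          # mean over neurons with defined R̄
    mean_feve: float           # mean over included neurons (FEV > threshold)
    n_included: int            # neurons entering mean_feve
    n_r_bar_defined: int
    fev_threshold: float = FEV_THRESHOLD

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "neuron_id": np.arange(len(self.r_bar)),
                "r_bar": self.r_bar,
                "fev": self.fev,
                "feve": self.feve,
                "included": ~np.isnan(self.feve) & (self.fev > self.fev_threshold),
            }
        )


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two (I, m) arrays -> (m,), NaN where
    either column is constant."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    num = (a * b).sum(axis=0)
    den = np.sqrt((a * a).sum(axis=0) * (b * b).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def correlation_to_average(table: RepeatTable) -> tuple[np.ndarray, float]:
    """Per-neuron Pearson correlation between predictions and repeat-averaged
    responses, plus its mean over neurons where it is defined."""
    if table.n_images < 2:
        raise ValueError("correlation to average needs at least two images")
    r = _pearson_rows(table.predictions, table.repeat_means())
    mean = float(np.nanmean(r)) if np.any(~np.isnan(r)) else float("nan")
    return r, mean


def _variance_components(table: RepeatTable, ddof: int = 0) -> tuple[np.ndarray, np.ndarray, int]:
    """Total variance over all N trials and mean within-image variance."""
    for i, r in enumerate(table.responses):
        if r.shape[0] < 2:
            raise ValueError(f"image {i} has {r.shape[0]} repeat(s); FEV/FEVE need >= 2")
    pooled = np.concatenate(table.responses, axis=0)
    total_var = pooled.var(axis=0, ddof=ddof)
    noise_var = np.mean([r.var(axis=0, ddof=ddof) for r in table.responses], axis=0)
    return total_var, noise_var, pooled.shape[0]


def fev(table: RepeatTable, ddof: int = 0) -> np.ndarray:
    """Per-neuron fraction of explainable variance,
    ``(Var[r] - sigma_eps^2) / Var[r]``; NaN where Var[r] = 0."""
    total_var, noise_var, _ = _variance_components(table, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (total_var - noise_var) / total_var
    out[total_var == 0] = np.nan
    return out


def feve(
    table: RepeatTable,
    fev_threshold: float = FEV_THRESHOLD,
    ddof: int = 0,
) -> tuple[np.ndarray, float, int]:
    """Per-neuron FEVE plus the aggregate mean over neurons with
    FEV > ``fev_threshold``.

    Returns ``(per_neuron_feve, mean_included, n_included)``. A neuron with
    non-positive explainable variance has undefined FEVE (NaN).
    """
    total_var, noise_var, n_trials = _variance_components(table, ddof=ddof)
    sq = np.zeros(table.n_neurons)
    for i, r in enumerate(table.responses):
        sq += ((r - table.predictions[i]) ** 2).sum(axis=0)
    mse = sq / n_trials
    explainable = total_var - noise_var
    with np.errstate(invalid="ignore", divide="ignore"):
        per = 1.0 - (mse - noise_var) / explainable
    per[explainable <= 0] = np.nan
    fev_vals = fev(table, ddof=ddof)
    included = ~np.isnan(per) & ~np.isnan(fev_vals) & (fev_vals > fev_threshold)
    mean = float(per[included].mean()) if included.any() else float("nan")
    return per, mean, int(included.sum())


def evaluate(table: RepeatTable, fev_threshold: float = FEV_THRESHOLD, ddof: int = 0) -> MetricReport:
    """Full metric report: R̄, FEV and FEVE with their aggregates."""
    r_bar, mean_r = correlation_to_average(table)
    fev_vals = fev(table, ddof=ddof)
    feve_vals, mean_feve, n_inc = feve(table, fev_threshold=fev_threshold, ddof=ddof)
    return MetricReport(
        r_bar=r_bar,
        fev=fev_vals,
        feve=feve_vals,
        mean_r_bar=mean_r,
        mean_feve=mean_feve,
        n_included=n_inc,
        n_r_bar_defined=int(np.sum(~np.isnan(r_bar))),
        fev_threshold=fev_threshold,
    )


def image_correlation(table: RepeatTable) -> tuple[np.ndarray, float]:
    """Per-image correlation across neurons between repeat-averaged responses
    and predictions (the transposed view of correlation-to-average)."""
    means = table.repeat_means()
    r = _pearson_rows(table.predictions.T, means.T)
    mean = float(np.nanmean(r)) if np.any(~np.isnan(r)) else float("nan")
    return r, mean


def table_from_trials(
    responses: np.ndarray,
    repeat_ids: np.ndarray,
    predictions: np.ndarray,
) -> RepeatTable:
    """Group per-trial responses (N, m) by stimulus identity into a
    :class:`RepeatTable`.

    ``predictions`` is per-trial (N, m); repeats of one stimulus must share a
    prediction (eval-mode models guarantee this), and the first trial's row is
    used per image.
    """
    responses = np.asarray(responses, dtype=np.float64)
    predictions = np.asarray(predictions, dtype=np.float64)
    repeat_ids = np.asarray(repeat_ids)
    if responses.shape != predictions.shape:
        raise ValueError("responses and predictions must align per trial")
    ids = np.unique(repeat_ids)
    grouped = []
    preds = []
    for sid in ids:
        mask = repeat_ids == sid
        grouped.append(responses[mask])
        preds.append(predictions[mask][0])
    return RepeatTable(responses=grouped, predictions=np.stack(preds))
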