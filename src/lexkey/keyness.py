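"""Keyness scoring with the log-odds ratio, informative Dirichlet prior.

For each lemma *w* the statistic compares its odds in a target corpus *i*
(counts ``y_i``, total ``n_i``) against a reference corpus *j*, after
smoothing both with pseudo-counts taken from the pooled corpora
(``alpha_w`` = pooled count of *w*, ``alpha_0`` = pooled total)::

    delta_w = log[(y_i + a_w) / (n_i + a_0 - (y_i + a_w))]
            - log[(y_j + a_w) / (n_j + a_0 - (y_j + a_w))]

    sigma2_w ~= 1/(y_i + a_w) + 1/(y_j + a_w)

    z_w = delta_w / sqrt(sigma2_w)

Positive z marks lemmas over-represented in (diagnostic of) the target
corpus, negative z lemmas diagnostic of the reference corpus.  Because
thousands of lemmas are tested at once, significance is declared against a
Bonferroni-corrected standard-normal quantile.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import KeynessDomainError
from .preprocess import CombinedLemmaTable

TAIL_CONVENTIONS = ("one-sided", "two-sided")


@dataclass
class KeynessResult:
    """Per-lemma keyness: counts, log-odds difference, variance, z, rank."""

    lemma: str
    y_target: int
    y_reference: int
    delta: float
    variance: float
    z: float
    significant: bool = False
    rank: int | None = None


@dataclass
class KeynessRun:
    """A complete scored run plus the multiplicity control that was applied."""

    results: list[KeynessResult]
    threshold_z: float
    alpha: float
    m: int
    tail_convention: str

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [dataclasses.asdict(r) for r in self.results],
            columns=["lemma", "y_target", "y_reference", "delta",
                     "variance", "z", "significant", "rank"],
        )
        frame["rank"] = frame["rank"].astype("Int64")
        return frame

    def metadata(self) -> dict:
        return {
            "alpha": self.alpha,
            "m": self.m,
            "threshold_z": self.threshold_z,
            "tail_convention": self.tail_convention,
        }

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the results TSV and a JSON metadata sidecar; return paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results_path = out / "keyness_results.tsv"
        meta_path = out / "keyness_run.json"
        self.to_frame().to_csv(results_path, sep="\t", index=False)
        meta_path.write_text(
            json.dumps(self.metadata(), indent=2) + "\n", encoding="utf-8"
        )
        return {"results": results_path, "metadata": meta_path}


# ---------------------------------------------------------------------------
# The statistic
# ---------------------------------------------------------------------------

def loridp_delta(y_i, n_i, y_j, n_j, alpha_w, alpha_0):
    """Smoothed log-odds difference delta_w between target and reference.

    Accepts scalars or aligned numpy arrays; natural-log units.  Raises
    :class:`KeynessDomainError` when a smoothed count or a smoothed
    complement is non-positive (degenerate one-lemma corpus).
    """
    num_i = np.asarray(y_i, dtype=float) + alpha_w
    num_j = np.asarray(y_j, dtype=float) + alpha_w
    den_i = np.asarray(n_i, dtype=float) + alpha_0 - num_i
    den_j = np.asarray(n_j, dtype=float) + alpha_0 - num_j
    if np.any(num_i <= 0) or np.any(num_j <= 0):
        raise KeynessDomainError("smoothed count y + alpha_w must be positive")
    if np.any(den_i <= 0) or np.any(den_j <= 0):
        raise KeynessDomainError(
            "smoothed complement n + alpha_0 - (y + alpha_w) must be positive"
        )
    result = np.log(num_i / den_i) - np.log(num_j / den_j)
    return result if result.ndim else float(result)


def loridp_variance(y_i, y_j, alpha_w):
    """Approximate variance of delta_w: 1/(y_i+a_w) + 1/(y_j+a_w)."""
    num_i = np.asarray(y_i, dtype=float) + alpha_w
    num_j = np.asarray(y_j, dtype=float) + alpha_w
    if np.any(num_i <= 0) or np.any(num_j <= 0):
        raise KeynessDomainError("smoothed count y + alpha_w must be positive")
    result = 1.0 / num_i + 1.0 / num_j
    return result if result.ndim else float(result)


def keyness_scores(
    table: CombinedLemmaTable,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (delta, variance, z) arrays for every row of the table.

    This is the numerical core that :func:`compute_keyness` wraps; simulation
    studies use it directly to avoid building per-lemma objects.
    """
    alpha_w = table.alpha_w
    try:
        delta = loridp_delta(
            table.y_target, table.n_target,
            table.y_reference, table.n_reference,
            alpha_w, table.alpha_0,
        )
        variance = loridp_variance(table.y_target, table.y_reference, alpha_w)
    except KeynessDomainError as exc:
        raise KeynessDomainError(
            f"{exc} (table with {table.n_rows} rows, first offending lemma: "
            f"{_first_offender(table)})"
        ) from exc
    return delta, variance, delta / np.sqrt(variance)


def _first_offender(table: CombinedLemmaTable) -> str:
    alpha_w = table.alpha_w
    num_t = table.y_target + alpha_w
    num_r = table.y_reference + alpha_w
    den_t = table.n_target + table.alpha_0 - num_t
    den_r = table.n_reference + table.alpha_0 - num_r
    bad = (num_t <= 0) | (num_r <= 0) | (den_t <= 0) | (den_r <= 0)
    index = int(np.argmax(bad))
    return table.lemmas[index] if bad.any() else "<none>"


def compute_keyness(table: CombinedLemmaTable) -> list[KeynessResult]:
    """Score every lemma of a combined table; no significance or rank yet."""
    delta, variance, z = keyness_scores(table)
    return [
        KeynessResult(
            lemma=table.lemmas[i],
            y_target=int(table.y_target[i]),
            y_reference=int(table.y_reference[i]),
            delta=float(delta[i]),
            variance=float(variance[i]),
            z=float(z[i]),
        )
        for i in range(table.n_rows)
    ]


# ---------------------------------------------------------------------------
# Multiplicity control and selection
# ---------------------------------------------------------------------------

def bonferroni_threshold(
    alpha: float, m: int, tail_convention: str = "one-sided"
) -> float:
    """Bonferroni-corrected standard-normal z threshold for m tests.

    ``one-sided`` returns the upper quantile at ``alpha/m``; ``two-sided``
    at ``alpha/(2m)``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValueError(f"m must be a positive integer, got {m!r}")
    if tail_convention not in TAIL_CONVENTIONS:
        raise ValueError(
            f"tail_convention must be one of {TAIL_CONVENTIONS}, "
            f"got {tail_convention!r}"
        )
    per_test = alpha / m
    if tail_convention == "two-sided":
        per_test /= 2.0
    return float(norm.isf(per_test))


def select_keys(
    results: list[KeynessResult], threshold: float
) -> tuple[list[KeynessResult], list[KeynessResult]]:
    """Split significant lemmas into target-diagnostic and reference-diagnostic.

    Flags every result (``significant`` iff ``|z| >= threshold``), then
    returns the target keys sorted by descending z and the reference keys by
    ascending z, with ranks 1..k assigned within each list.  Equal z values
    are ordered alphabetically by lemma for determinism.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    for result in results:
        result.significant = abs(result.z) >= threshold
        result.rank = None
    target = sorted(
        (r for r in results if r.z >= threshold),
        key=lambda r: (-r.z, r.lemma),
    )
    reference = sorted(
        (r for r in results if r.z <= -threshold),
        key=lambda r: (r.z, r.lemma),
    )
    for rank, result in enumerate(target, start=1):
        result.rank = rank
    for rank, result in enumerate(reference, start=1):
        result.rank = rank
    return target, reference


def top_k_table(
    keys: list[KeynessResult],
    k: int,
    gloss_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """First min(k, len) ranked keys as a (rank, lemma, gloss, abs_z) table."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    gloss_map = gloss_map or {}
    rows = [
        {
            "rank": r.rank if r.rank is not None else index,
            "lemma": r.lemma,
            "gloss": gloss_map.get(r.lemma, ""),
            "abs_z": abs(r.z),
        }
        for index, r in enumerate(keys[:k], start=1)
    ]
    return pd.DataFrame(rows, columns=["rank", "lemma", "gloss", "abs_z"])
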