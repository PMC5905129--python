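"""Mass isotopologue distribution (MID) arithmetic.

Natural-abundance correction, relative quantification against an internal
standard and cell number, and per-metabolite labeling indices (fractional
contribution / percent label).

Conventions
-----------
An MID for a metabolite with ``n`` traceable atoms is a non-negative vector
``M_0 .. M_n`` of isotopologue intensities, where ``M_i`` is the signal
observed at a nominal mass shift of ``i`` heavy-atom units.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "NATURAL_ABUNDANCE",
    "parse_formula",
    "build_correction_matrix",
    "correct_natural_abundance",
    "relative_amount",
    "fractional_contribution",
    "normalize_tracer_enrichment",
    "MIDPanel",
    "LabelingIndexTable",
    "labeling_index_table",
    "relative_amounts",
]

# Per-element distribution of nominal mass shift for one atom:
# {mass shift in Da units: probability}.  Values are IUPAC-representative
# terrestrial abundances.
NATURAL_ABUNDANCE: dict[str, dict[int, float]] = {
    "C": {0: 0.9893, 1: 0.0107},
    "H": {0: 0.999885, 1: 0.000115},
    "N": {0: 0.99636, 1: 0.00364},
    "O": {0: 0.99757, 1: 0.00038, 2: 0.00205},
    "S": {0: 0.9499, 1: 0.0075, 2: 0.0425},
    "P": {0: 1.0},
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse an elemental formula like ``"C6H12O6"`` into element counts."""
    if isinstance(formula, Mapping):
        counts = {str(k): int(v) for k, v in formula.items()}
    else:
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
    for el, n in counts.items():
        if n < 0:
            raise ValueError(f"negative atom count for {el}")
    return counts


def _atom_shift_dist(element: str, abundances: Mapping[str, Mapping[int, float]]) -> np.ndarray:
    if element not in abundances:
        raise ValueError(f"unknown element {element!r}: no natural-abundance table")
    table = abundances[element]
    dist = np.zeros(max(table) + 1)
    for shift, p in table.items():
        dist[shift] = p
    return dist


def _convolve_power(dist: np.ndarray, n: int, length: int) -> np.ndarray:
    """Shift distribution of ``n`` i.i.d. atoms, truncated to ``length`` bins."""
    out = np.zeros(length)
    out[0] = 1.0
    for _ in range(n):
        out = np.convolve(out, dist)[:length]
    return out


def build_correction_matrix(
    formula: str | Mapping[str, int],
    tracer_element: str = "C",
    abundances: Mapping[str, Mapping[int, float]] | None = None,
) -> np.ndarray:
    """Forward natural-abundance convolution matrix for one metabolite.

    Entry ``(i, j)`` is the probability that a molecule carrying ``j``
    tracer-labeled atoms is observed at nominal mass shift ``i``.  The
    ``n - j`` unlabeled tracer atoms contribute binomial natural abundance;
    every non-tracer atom contributes its own single-atom shift
    distribution.  Mass shifts beyond ``n`` are truncated, so column sums
    may fall below 1.

    Multiplying this matrix onto a natural-abundance-free MID yields the
    expected observed MID; :func:`correct_natural_abundance` inverts it.
    """
    counts = parse_formula(formula)
    if abundances is None:
        abundances = NATURAL_ABUNDANCE
    n = counts.get(tracer_element, 0)
    if n < 1:
        raise ValueError(
            f"formula has no {tracer_element!r} atoms; cannot build a correction matrix"
        )
    size = n + 1

    # Mass-shift distribution contributed by all non-tracer atoms combined.
    other = np.zeros(size)
    other[0] = 1.0
    for el, k in counts.items():
        if el == tracer_element or k == 0:
            continue
        other = np.convolve(other, _convolve_power(_atom_shift_dist(el, abundances), k, size))[:size]

    tracer_dist = _atom_shift_dist(tracer_element, abundances)
    if len(tracer_dist) > 2:
        raise ValueError(f"tracer element {tracer_element!r} must have a two-isotope table")
    p_heavy = tracer_dist[1] if len(tracer_dist) == 2 else 0.0

    C = np.zeros((size, size))
    for j in range(size):
        # j labeled atoms fix a shift of j; the remaining n-j atoms are
        # binomial in the heavy isotope.
        unlabeled = np.zeros(size)
        ks = np.arange(n - j + 1)
        unlabeled[: n - j + 1] = binom.pmf(ks, n - j, p_heavy)
        col = np.convolve(unlabeled, other)[:size]
        C[j:, j] = col[: size - j]
    return C


def correct_natural_abundance(
    raw: np.ndarray, C: np.ndarray, max_condition: float = 1e8
) -> np.ndarray:
    """Invert the natural-abundance convolution ``C @ x = raw``.

    Solves by least squares; negative components (noise artifacts) are
    clipped to zero and the vector rescaled to preserve the estimated
    total, so that exact forward-convolved inputs round-trip unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correction matrix must be square")
    if raw.shape != (C.shape[0],):
        raise ValueError(f"MID length {raw.shape} does not match matrix {C.shape}")
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > max_condition:
        raise np.linalg.LinAlgError(
            f"correction matrix is ill-conditioned (condition number {cond:.3g})"
        )
    if not raw.any():
        return np.zeros_like(raw)
    x, *_ = np.linalg.lstsq(C, raw, rcond=None)
    if (x < 0).any():
        total = x.sum()
        x = np.clip(x, 0.0, None)
        if x.sum() > 0 and total > 0:
            x *= total / x.sum()
    return x


def relative_amount(mid: np.ndarray, internal_standard: float, cell_count: int) -> float:
    """Total isotopologue signal normalized to internal standard and cell number."""
    if internal_standard <= 0:
        raise ValueError("internal-standard intensity must be positive")
    if cell_count <= 0:
        raise ValueError("cell count must be positive")
    mid = np.asarray(mid, dtype=float)
    return float(mid.sum() / (internal_standard * cell_count))


def fractional_contribution(
    mid: np.ndarray, n_atoms: int, mode: str = "fractional"
) -> float:
    """Single labeling index summarizing an MID.

    ``"fractional"`` weights isotopologues by their heavy-atom count:
    ``sum(i * M_i) / (n * sum(M_i))``.  ``"one_minus_m0"`` is the fraction
    of molecules with at least one heavy atom: ``1 - M_0 / sum(M_i)``.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    mid = np.asarray(mid, dtype=float)
    if mid.shape != (n_atoms + 1,):
        raise ValueError(f"MID length {mid.shape[0]} != n_atoms+1 = {n_atoms + 1}")
    total = mid.sum()
    if total <= 0:
        raise ValueError("zero total intensity: fractional contribution undefined")
    if mode == "fractional":
        fc = float(np.arange(n_atoms + 1) @ mid / (n_atoms * total))
    elif mode == "one_minus_m0":
        fc = float(1.0 - mid[0] / total)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return min(max(fc, 0.0), 1.0)


def normalize_tracer_enrichment(fc: float, e: float, tol: float = 0.05) -> float:
    """Rescale a labeling index by the tracer enrichment ``e`` of the medium.

    With a 50 %-enriched tracer the maximum attainable index is 0.5; this
    maps it back onto [0, 1].  Values marginally above ``e`` (noise) are
    clipped to 1 with a warning.
    """
    if e <= 0 or e > 1:
        raise ValueError("tracer enrichment must lie in (0, 1]")
    if fc < 0 or fc > e + tol:
        raise ValueError(f"labeling index {fc} outside [0, {e}] + tolerance")
    if fc > e:
        warnings.warn(
            f"labeling index {fc:.4g} exceeds tracer enrichment {e}; clipping to 1",
            stacklevel=2,
        )
        return 1.0
    return fc / e


@dataclass
class MIDPanel:
    """Per-metabolite isotopologue intensities across samples.

    Attributes
    ----------
    data:
        Rows indexed by ``(metabolite, isotopologue_index)``, one column per
        sample.  Each metabolite block has ``n_atoms + 1`` rows.
    formulas:
        Metabolite -> elemental formula string.
    samples:
        Per-sample frame with ``internal_standard_intensity`` and
        ``cell_count`` columns (``group`` optional).
    """

    data: pd.DataFrame
    formulas: pd.Series
    samples: pd.DataFrame
    tracer_element: str = "C"
    tracer_enrichment: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.MultiIndex) or self.data.index.nlevels != 2:
            raise ValueError("data must be indexed by (metabolite, isotopologue_index)")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("isotopologue intensities must be finite")
        if (vals < 0).any():
            raise ValueError("negative isotopologue intensities rejected")
        missing = set(self.data.index.get_level_values(0)) - set(self.formulas.index)
        if missing:
            raise ValueError(f"metabolites without formulas: {sorted(missing)}")
        for col in ("internal_standard_intensity", "cell_count"):
            if col not in self.samples.columns:
                raise ValueError(f"samples frame lacks {col!r}")
        if (self.samples["internal_standard_intensity"] <= 0).any():
            raise ValueError("internal-standard intensities must be positive")
        if (self.samples["cell_count"] <= 0).any():
            raise ValueError("cell counts must be positive")
        if not (0 < self.tracer_enrichment <= 1):
            raise ValueError("tracer enrichment must lie in (0, 1]")

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.index.get_level_values(0).unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def n_atoms(self, metabolite: str) -> int:
        counts = parse_formula(self.formulas[metabolite])
        n = counts.get(self.tracer_element, 0)
        if n < 1:
            raise ValueError(f"{metabolite} has no {self.tracer_element} atoms")
        return n

    def mid(self, metabolite: str, sample: str) -> np.ndarray:
        """Dense MID vector ``M_0..M_n``; missing isotopologue rows count as zero."""
        n = self.n_atoms(metabolite)
        block = self.data.loc[metabolite, sample]
        out = np.zeros(n + 1)
        idx = np.asarray(block.index, dtype=int)
        if (idx < 0).any() or (idx > n).any():
            raise ValueError(f"isotopologue index out of range for {metabolite}")
        if len(idx) < n + 1:
            warnings.warn(
                f"{metabolite}/{sample}: missing isotopologue rows treated as zero",
                stacklevel=2,
            )
        out[idx] = block.to_numpy(dtype=float)
        return out


@dataclass
class LabelingIndexTable:
    """Labeling indices (metabolite x sample) with per-cell validity flags."""

    values: pd.DataFrame
    valid: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid flags must be aligned")

    def drop_invalid(self) -> pd.DataFrame:
        """Rows where every sample has a valid index (listwise deletion)."""
        return self.values.loc[self.valid.all(axis=1)]


def _corrected_mid(panel: MIDPanel, metabolite: str, sample: str, correct_na: bool) -> np.ndarray:
    raw = panel.mid(metabolite, sample)
    if not correct_na:
        return raw
    C = build_correction_matrix(panel.formulas[metabolite], panel.tracer_element)
    return correct_natural_abundance(raw, C)


def labeling_index_table(
    panel: MIDPanel,
    correct_na: bool = True,
    mode: str = "fractional",
    normalize_enrichment: bool = False,
) -> LabelingIndexTable:
    """Compute one labeling index per (metabolite, sample).

    Zero-intensity cells are flagged invalid rather than raising.  With
    ``normalize_enrichment`` the indices are divided by the panel's tracer
    enrichment (off by default: raw indices are what get clustered).
    """
    mets = panel.metabolites
    cols = panel.sample_ids
    values = pd.DataFrame(np.nan, index=mets, columns=cols)
    valid = pd.DataFrame(False, index=mets, columns=cols)
    corr_cache: dict[str, np.ndarray] = {}
    for met in mets:
        n = panel.n_atoms(met)
        if correct_na and met not in corr_cache:
            corr_cache[met] = build_correction_matrix(panel.formulas[met], panel.tracer_element)
        for s in cols:
            raw = panel.mid(met, s)
            if raw.sum() <= 0:
                continue
            mid_vec = correct_natural_abundance(raw, corr_cache[met]) if correct_na else raw
            if mid_vec.sum() <= 0:
                continue
            fc = fractional_contribution(mid_vec, n, mode=mode)
            if normalize_enrichment:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fc = normalize_tracer_enrichment(
                        min(fc, panel.tracer_enrichment * 1.05), panel.tracer_enrichment
                    )
            values.loc[met, s] = fc
            valid.loc[met, s] = True
    return LabelingIndexTable(values=values, valid=valid)


def relative_amounts(panel: MIDPanel) -> pd.DataFrame:
    """Relative metabolite amounts (metabolite x sample), per-cell units."""
    out = pd.DataFrame(index=panel.metabolites, columns=panel.sample_ids, dtype=float)
    for met in panel.metabolites:
        for s in panel.sample_ids:
            out.loc[met, s] = relative_amount(
                panel.mid(met, s),
                float(panel.samples.loc[s, "internal_standard_intensity"]),
                int(panel.samples.loc[s, "cell_count"]),
            )
    return out
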