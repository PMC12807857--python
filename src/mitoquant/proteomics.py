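"""Histone proteomic-ruler copy numbers and the differential-inheritance filter.

The proteomic ruler converts label-free MS intensities into per-cell
protein copy numbers without spike-in standards, exploiting the fixed
histone:DNA mass relationship of a cell: per sample,

    m_DNA   = genome_size_bp * ploidy * mean_bp_molar_mass / N_A
    copies_i = (I_i / sum_histones I) * m_DNA * N_A / M_i

so the summed histone protein mass per cell equals the DNA mass by
construction, and copy numbers are invariant to global per-sample intensity
scaling.

The differential-inheritance filter compares two sample groups on log2
intensities with the unequal-variance t-test; a protein is called
significant when p < 0.05 and its linear fold change exceeds 1.5 in either
direction (the lower gate is 1/1.5, making the filter exactly symmetric
under group swap; 0.67 is that value rounded). Proteins quantified in fewer
than two samples of either group are reported categorically as not
testable — zeros are treated as missing, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import welch_t_test

__all__ = [
    "RulerConfig",
    "copy_numbers",
    "differential_inheritance",
]

AVOGADRO = 6.02214076e23


@dataclass
class RulerConfig:
    """Constants of the histone ruler (defaults: diploid mouse genome)."""

    genome_size_bp: float = 2.7e9  # haploid
    ploidy: float = 2.0
    mean_bp_molar_mass: float = 615.8771  # g/mol per base pair
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if min(self.genome_size_bp, self.ploidy,
               self.mean_bp_molar_mass, self.avogadro) <= 0:
            raise ValueError("all ruler constants must be positive")

    @property
    def dna_mass_per_cell_g(self) -> float:
        return self.genome_size_bp * self.ploidy * self.mean_bp_molar_mass \
            / self.avogadro


def copy_numbers(
    table: pd.DataFrame,
    sample_columns: list[str],
    config: RulerConfig | None = None,
) -> pd.DataFrame:
    """Add per-sample copy-number and mass-fraction columns to a protein table.

    ``table`` needs columns ``protein_id``, ``is_histone`` (bool) and
    ``molar_mass`` (g/mol), plus one intensity column per sample. For each
    sample ``s`` the result gains ``copies_<s>`` and ``mass_fraction_<s>``.
    A sample without positive histone signal is uncomputable: its copies
    are NaN and it is listed in ``result.attrs["uncomputable_samples"]``.
    """
    config = config if config is not None else RulerConfig()
    for col in ("protein_id", "is_histone", "molar_mass"):
        if col not in table.columns:
            raise ValueError(f"protein table lacks required column {col!r}")
    if (table["molar_mass"] <= 0).any():
        raise ValueError("molar masses must be positive")
    out = table.copy()
    masses = out["molar_mass"].to_numpy(dtype=float)
    histone = out["is_histone"].to_numpy(dtype=bool)
    if not histone.any():
        raise ValueError("no histone-flagged proteins: the ruler cannot calibrate")
    uncomputable = []
    m_dna = config.dna_mass_per_cell_g
    for s in sample_columns:
        intens = out[s].to_numpy(dtype=float)
        if (intens < 0).any():
            raise ValueError(f"negative intensities in sample {s!r}")
        hist_sum = intens[histone].sum()
        total = intens.sum()
        out[f"mass_fraction_{s}"] = intens / total if total > 0 else np.nan
        if hist_sum <= 0:
            uncomputable.append(s)
            out[f"copies_{s}"] = np.nan
            continue
        out[f"copies_{s}"] = (intens / hist_sum) * m_dna * config.avogadro / masses
    out.attrs["uncomputable_samples"] = uncomputable
    out.attrs["dna_mass_per_cell_g"] = m_dna
    return out


def differential_inheritance(
    table: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    fc_gate: float = 1.5,
) -> pd.DataFrame:
    """Two-group differential test on log2 intensities with the fold-change gate.

    Per protein: zeros are excluded as missing; with >= 2 positive values in
    each group, the fold change is the ratio of group geometric means
    (``2**(mean log2 A - mean log2 B)``) and p comes from the Welch t-test
    on the log2 values. ``significant`` requires BOTH ``p < alpha`` AND
    ``FC > fc_gate or FC < 1/fc_gate``. Proteins not quantified in enough
    samples are returned with ``testable = False`` (mirroring categorical
    present/absent reporting rather than imputation).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 sample columns")
    rows = []
    for _, rec in table.iterrows():
        a = np.asarray([rec[c] for c in group_a], dtype=float)
        b = np.asarray([rec[c] for c in group_b], dtype=float)
        a = a[a > 0]
        b = b[b > 0]
        row = {"protein_id": rec["protein_id"]}
        if len(a) < 2 or len(b) < 2:
            row.update(
                testable=False, fold_change=np.nan, log2_fc=np.nan,
                p_value=np.nan, significant=False,
                n_a=len(a), n_b=len(b),
            )
            rows.append(row)
            continue
        la, lb = np.log2(a), np.log2(b)
        log2_fc = float(la.mean() - lb.mean())
        fc = float(2.0**log2_fc)
        res = welch_t_test(la, lb, two_sided=True)
        significant = (res.p_value < alpha) and (fc > fc_gate or fc < 1.0 / fc_gate)
        row.update(
            testable=True, fold_change=fc, log2_fc=log2_fc,
            p_value=res.p_value, significant=bool(significant),
            n_a=len(a), n_b=len(b),
        )
        rows.append(row)
    return pd.DataFrame(rows)
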