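"""Intensity-weighted N/Q deamidation rate with bootstrap confidence intervals.

The statistic, computed separately for asparagine (N) and glutamine (Q):

1.  For each PSM, the deamidated fraction of the class is
    ``num_deamidated / num_residues`` for the peptide's N (or Q) residues;
    PSMs whose peptide has no residue of the class are excluded for that
    class.
2.  Within one raw file, PSMs sharing the same plain (unmodified) sequence
    and charge are pooled: the peptide/charge rate is
    ``sum(fraction_i * intensity_i) / sum(intensity_i)`` over *all* PSMs of
    the group, modified and unmodified alike — which is what keeps the rate
    in [0, 1].  PSMs without an intensity carry no weight but still count as
    scans.
3.  Per peptide, rates are averaged (unweighted) over its charge states; per
    raw file, peptide rates are averaged (unweighted) into the sample rate.
4.  The per-peptide rates are resampled with replacement (1000 times by
    default); the mean, standard deviation and 2.5/97.5 percentile interval
    of the bootstrap means are reported on the percent scale.

The estimator is exposed statsmodels-style: build a :class:`DeamidationModel`
from PSM records (or an evidence-dialect DataFrame), call :meth:`fit`, and
read estimates, uncertainties and diagnostics off the returned
:class:`DeamidationResults`, whose :meth:`~DeamidationResults.summary` prints
a per-raw-file table and whose :meth:`~DeamidationResults.to_files` writes
the four delimited output files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import evidence as _evidence
from .errors import ConfigurationError, DataError
from .evidence import PSMRecord, write_deamidation_outputs
from .modifications import ModificationRegistry, default_registry

RESIDUE_CLASSES = ("N", "Q")
DEFAULT_SEED = 1218
DEFAULT_N_BOOT = 1000


@dataclass(frozen=True)
class PSMDeamidationFractions:
    """Per-PSM residue counts and deamidated fractions for N and Q.

    ``ratio_N2D``/``ratio_Q2E`` are ``None`` when the peptide has no residue
    of that class; such PSMs are excluded from the class downstream.
    """

    num_N: int
    num_N2D: int
    num_Q: int
    num_Q2E: int
    intensity: Optional[float]

    def __post_init__(self):
        if self.num_N2D > self.num_N or self.num_Q2E > self.num_Q:
            raise DataError("more deamidated residues than residues")

    @property
    def ratio_N2D(self) -> Optional[float]:
        return self.num_N2D / self.num_N if self.num_N else None

    @property
    def ratio_Q2E(self) -> Optional[float]:
        return self.num_Q2E / self.num_Q if self.num_Q else None

    def ratio(self, residue_class: str) -> Optional[float]:
        return {"N": self.ratio_N2D, "Q": self.ratio_Q2E}[residue_class]

    def count(self, residue_class: str) -> int:
        return {"N": self.num_N, "Q": self.num_Q}[residue_class]


def psm_fractions(record: PSMRecord, mod_name: str = "deamidation") -> PSMDeamidationFractions:
    """Counts and deamidated fractions of one PSM, attributed by residue."""
    positions = record.modified_positions(mod_name)
    n2d = sum(1 for p in positions if p >= 1 and record.sequence[p - 1] == "N")
    q2e = sum(1 for p in positions if p >= 1 and record.sequence[p - 1] == "Q")
    return PSMDeamidationFractions(
        num_N=record.sequence.count("N"),
        num_N2D=n2d,
        num_Q=record.sequence.count("Q"),
        num_Q2E=q2e,
        intensity=record.intensity,
    )


def peptide_rate(
    fractions: Sequence[PSMDeamidationFractions], residue_class: str
) -> float:
    """Intensity-weighted deamidation rate of one (sequence, charge) group.

    All PSMs of the group — deamidated or not — enter the denominator; PSMs
    with missing intensity are skipped.  Undefined when no PSM has both an
    eligible residue and an intensity.
    """
    if residue_class not in RESIDUE_CLASSES:
        raise ConfigurationError(f"residue class must be N or Q, got {residue_class!r}")
    num = den = 0.0
    any_weight = False
    for frac in fractions:
        ratio = frac.ratio(residue_class)
        if ratio is None or frac.intensity is None:
            continue
        num += ratio * frac.intensity
        den += frac.intensity
        any_weight = True
    if not any_weight or den == 0:
        raise DataError(
            f"rate undefined: no PSM with residue class {residue_class} and "
            "a present intensity"
        )
    return num / den


def sample_rates(
    records: Iterable[PSMRecord], raw_file: str, residue_class: str,
    mod_name: str = "deamidation",
) -> dict:
    """Per-peptide rates within one raw file (charge states averaged).

    Returns a mapping ``plain sequence -> rate``; the sample mean is the
    unweighted mean of these values.
    """
    groups: dict[tuple, list] = {}
    for rec in records:
        if rec.raw_file != raw_file:
            continue
        frac = psm_fractions(rec, mod_name)
        if frac.ratio(residue_class) is None:
            continue
        groups.setdefault((rec.sequence, rec.charge), []).append(frac)
    per_charge: dict[str, list] = {}
    for (sequence, _charge), fracs in groups.items():
        try:
            rate = peptide_rate(fracs, residue_class)
        except DataError:
            continue  # all intensities missing in this charge group
        per_charge.setdefault(sequence, []).append(rate)
    return {seq: sum(rs) / len(rs) for seq, rs in per_charge.items()}


def bootstrap_ci(
    values: Sequence[float],
    n_boot: int = DEFAULT_N_BOOT,
    seed: Union[int, np.random.Generator] = DEFAULT_SEED,
    ci_method: str = "percentile",
) -> tuple:
    """Bootstrap mean, SD and 95% CI of the mean of ``values``.

    Resamples with replacement ``n_boot`` times; the per-draw statistic is
    the mean.  Returns ``(mean, sd, ci_low, ci_high, draws)`` where mean and
    sd are taken over the draws and the interval is the 2.5/97.5 percentile
    range (``ci_method="percentile"``, the only method currently provided,
    kept as an explicit knob).
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise DataError("cannot bootstrap an empty value list")
    if n_boot < 1:
        raise ConfigurationError(f"n_boot must be >= 1, got {n_boot}")
    if ci_method != "percentile":
        raise ConfigurationError(f"unknown ci_method {ci_method!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    draws = values[idx].mean(axis=1)
    if np.ptp(draws) == 0.0:  # degenerate resampling (e.g. a single value)
        sd = 0.0
    else:
        sd = float(draws.std(ddof=1)) if n_boot > 1 else 0.0
    ci_low, ci_high = np.percentile(draws, [2.5, 97.5])
    return float(draws.mean()), sd, float(ci_low), float(ci_high), draws


def _class_rng(seed: int, *labels) -> np.random.Generator:
    """A generator keyed on (seed, labels) so results do not depend on the
    order in which raw files or classes are processed."""
    key = [int(seed)] + [zlib.crc32(str(l).encode()) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(key))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class DeamidationModel:
    """Deamidation-rate estimator over a PSM evidence set.

    Parameters
    ----------
    evidence
        Either a list of :class:`~ptmquant.evidence.PSMRecord` or a
        DataFrame in the evidence dialect (columns "Sequence",
        "Modified sequence", "Charge", "Intensity", "Raw file", optionally
        "Leading razor protein").
    registry
        Modification registry used to parse inline tokens; defaults to the
        built-in set.
    mod_name
        Registry name of the deamidation modification.
    """

    def __init__(
        self,
        evidence: Union[Sequence[PSMRecord], pd.DataFrame],
        registry: Optional[ModificationRegistry] = None,
        mod_name: str = "deamidation",
    ):
        self.registry = registry or default_registry()
        self.mod_name = mod_name
        self._frame = self._build_frame(evidence)

    # -- input normalisation ------------------------------------------------
    def _build_frame(self, evidence) -> pd.DataFrame:
        if isinstance(evidence, pd.DataFrame):
            return self._frame_from_dataframe(evidence)
        rows = []
        for rec in evidence:
            frac = psm_fractions(rec, self.mod_name)
            rows.append(
                (rec.raw_file, rec.sequence, rec.charge, rec.intensity,
                 rec.leading_razor_protein or (rec.proteins[0] if rec.proteins else ""),
                 frac.num_N, frac.num_N2D, frac.num_Q, frac.num_Q2E)
            )
        return pd.DataFrame(
            rows,
            columns=["raw_file", "sequence", "charge", "intensity", "protein",
                     "num_N", "num_N2D", "num_Q", "num_Q2E"],
        )

    def _frame_from_dataframe(self, frame: pd.DataFrame) -> pd.DataFrame:
        dialect = _evidence.DEFAULT_DIALECT
        for fieldname in _evidence.REQUIRED_FIELDS:
            if dialect[fieldname] not in frame.columns:
                raise ConfigurationError(
                    f"evidence frame is missing column {dialect[fieldname]!r}"
                )
        # Parse each distinct modified sequence once; evidence tables repeat
        # the same precursor across PSMs, so this is the fast path.
        parsed = {}
        for modseq in frame[dialect["modified_sequence"]].unique():
            plain, mods = _evidence.parse_modified_sequence(modseq, self.registry)
            n2d = sum(1 for n, p in mods
                      if n == self.mod_name and p >= 1 and plain[p - 1] == "N")
            q2e = sum(1 for n, p in mods
                      if n == self.mod_name and p >= 1 and plain[p - 1] == "Q")
            parsed[modseq] = (plain, plain.count("N"), n2d, plain.count("Q"), q2e)
        info = frame[dialect["modified_sequence"]].map(parsed)
        protein_col = dialect["leading_razor_protein"]
        proteins = (
            frame[protein_col].fillna("").astype(str)
            if protein_col in frame.columns
            else pd.Series("", index=frame.index)
        )
        return pd.DataFrame(
            {
                "raw_file": frame[dialect["raw_file"]].astype(str),
                "sequence": info.str[0],
                "charge": pd.to_numeric(frame[dialect["charge"]]).astype(int),
                "intensity": pd.to_numeric(
                    frame[dialect["intensity"]], errors="coerce"
                ),
                "protein": proteins,
                "num_N": info.str[1],
                "num_N2D": info.str[2],
                "num_Q": info.str[3],
                "num_Q2E": info.str[4],
            }
        )

    # -- estimation ---------------------------------------------------------
    @staticmethod
    def _group_rates(sub: pd.DataFrame, residue_class: str) -> pd.Series:
        """Per-peptide rates (charge-averaged) for one raw file and class."""
        eligible = sub[sub[f"num_{residue_class}"] > 0]
        weighted = eligible.dropna(subset=["intensity"]).copy()
        if weighted.empty:
            return pd.Series(dtype=float)
        weighted["fraction"] = (
            weighted[f"num_{residue_class}2{'D' if residue_class == 'N' else 'E'}"]
            / weighted[f"num_{residue_class}"]
        )
        weighted["weighted"] = weighted["fraction"] * weighted["intensity"]
        grouped = weighted.groupby(["sequence", "charge"], sort=True).agg(
            num=("weighted", "sum"), den=("intensity", "sum")
        )
        grouped = grouped[grouped["den"] > 0]
        rates = grouped["num"] / grouped["den"]
        return rates.groupby(level="sequence").mean()

    def fit(
        self,
        n_boot: int = DEFAULT_N_BOOT,
        seed: int = DEFAULT_SEED,
        ci_method: str = "percentile",
        min_scans: int = 1,
    ) -> "DeamidationResults":
        """Estimate per-raw-file (and per-protein) deamidation rates.

        ``min_scans`` suppresses raw-file/class cells with fewer eligible
        PSMs than requested (they are reported with zero estimates, like
        empty classes).  Results are fully reproducible given ``seed`` and
        invariant to the row order of the evidence.
        """
        frame = self._frame
        rows, boot_draws, peptide_rows, count_rows = [], {}, [], []
        for raw_file in sorted(frame["raw_file"].unique()):
            sub = frame[frame["raw_file"] == raw_file]
            counts = {"Raw file": raw_file}
            for residue_class in RESIDUE_CLASSES:
                n_scans = int((sub[f"num_{residue_class}"] > 0).sum())
                rates = self._group_rates(sub, residue_class)
                counts[f"N_peptides_{residue_class}"] = int(rates.size)
                if rates.empty or n_scans < min_scans:
                    mean = sd = lo = hi = 0.0
                    draws = np.zeros(n_boot)
                else:
                    rng = _class_rng(seed, raw_file, residue_class)
                    mean, sd, lo, hi, draws = bootstrap_ci(
                        rates.to_numpy() * 100.0, n_boot, rng, ci_method
                    )
                rows.append(
                    {"Raw file": raw_file, "Residue": residue_class,
                     "Mean": mean, "Std": sd, "CI_low": lo, "CI_up": hi,
                     "N_scans": n_scans}
                )
                boot_draws[(raw_file, residue_class)] = draws
                for sequence, rate in rates.items():
                    peptide_rows.append(
                        {"Raw file": raw_file, "Residue": residue_class,
                         "Sequence": sequence, "Rate": float(rate)}
                    )
            counts["N_PSMs"] = int(len(sub))
            count_rows.append(counts)

        protein_rows = []
        for (protein, raw_file), sub in frame.groupby(["protein", "raw_file"], sort=True):
            if not protein:
                continue
            for residue_class in RESIDUE_CLASSES:
                n_scans = int((sub[f"num_{residue_class}"] > 0).sum())
                rates = self._group_rates(sub, residue_class)
                if rates.empty or n_scans < min_scans:
                    mean = sd = lo = hi = 0.0
                else:
                    rng = _class_rng(seed, protein, raw_file, residue_class)
                    mean, sd, lo, hi, _ = bootstrap_ci(
                        rates.to_numpy() * 100.0, n_boot, rng, ci_method
                    )
                protein_rows.append(
                    {"Protein": protein, "Raw file": raw_file,
                     "Residue": residue_class, "Mean": mean, "Std": sd,
                     "CI_low": lo, "CI_up": hi, "N_scans": n_scans}
                )

        return DeamidationResults(
            model=self,
            table=pd.DataFrame(
                rows, columns=["Raw file", "Residue", "Mean", "Std",
                               "CI_low", "CI_up", "N_scans"],
            ),
            peptide_rates=pd.DataFrame(
                peptide_rows, columns=["Raw file", "Residue", "Sequence", "Rate"]
            ),
            peptide_counts=pd.DataFrame(
                count_rows, columns=["Raw file", "N_peptides_N",
                                     "N_peptides_Q", "N_PSMs"]
            ),
            protein_table=pd.DataFrame(
                protein_rows, columns=["Protein", "Raw file", "Residue", "Mean",
                                       "Std", "CI_low", "CI_up", "N_scans"]
            ),
            bootstrap_draws=boot_draws,
            n_boot=n_boot,
            seed=seed,
            ci_method=ci_method,
        )


@dataclass
class DeamidationResults:
    """Fitted deamidation-rate estimates.

    ``table`` holds one row per raw file and residue class with the bootstrap
    mean, SD and 95% CI bounds on the percent scale plus the scan count;
    ``peptide_rates`` the underlying per-peptide rates (on the 0–1 scale);
    ``protein_table`` the same summary aggregated per protein accession;
    ``bootstrap_draws`` every bootstrap draw per (raw file, class).
    """

    model: DeamidationModel
    table: pd.DataFrame
    peptide_rates: pd.DataFrame
    peptide_counts: pd.DataFrame
    protein_table: pd.DataFrame
    bootstrap_draws: dict
    n_boot: int
    seed: int
    ci_method: str

    def sample_mean(self, raw_file: str, residue_class: str) -> float:
        """Plain (non-bootstrap) sample mean of per-peptide rates, in percent."""
        sel = self.peptide_rates[
            (self.peptide_rates["Raw file"] == raw_file)
            & (self.peptide_rates["Residue"] == residue_class)
        ]["Rate"]
        return float(sel.mean() * 100.0) if sel.size else 0.0

    def ci(self, raw_file: str, residue_class: str) -> tuple:
        row = self.table[
            (self.table["Raw file"] == raw_file)
            & (self.table["Residue"] == residue_class)
        ].iloc[0]
        return float(row["CI_low"]), float(row["CI_up"])

    def summary(self) -> str:
        lines = [
            "Deamidation rate estimates (percent scale)",
            f"bootstrap: n_boot={self.n_boot}, seed={self.seed}, "
            f"ci={self.ci_method} (2.5/97.5)",
            "",
            self.table.to_string(
                index=False,
                formatters={c: "{:.4f}".format
                            for c in ("Mean", "Std", "CI_low", "CI_up")},
            ),
        ]
        return "\n".join(lines)

    def to_files(self, out_dir, header_comment: Optional[str] = None):
        """Write Deamidation.txt, Number_of_Peptides_per_RawFile.txt,
        Bootstrapped_values.txt and Protein_deamidation.txt."""
        return write_deamidation_outputs(self, out_dir, header_comment)
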