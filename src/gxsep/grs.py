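"""Unweighted genetic risk allele sum scores (GRS).

A GRS here is the plain count of risk alleles an individual carries across a
fixed SNP panel: for each panel SNP the imputed dosage of the risk allele
(a value in [0, 2]) is summed, so a 10-SNP panel yields scores in [0, 20].
Panels may declare a proxy marker per SNP — a correlated SNP (LD r²) whose
dosage substitutes for samples where the primary marker is missing.

Dosages are summed as-is (fractional values from imputation are kept);
``hard_call=True`` rounds to the nearest integer genotype first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelEntry",
    "SnpPanel",
    "GrsResult",
    "compute_grs",
    "apply_proxy",
    "tertiles",
    "TERTILE_LABELS",
]

TERTILE_LABELS = ("lower", "middle", "highest")

MissingPolicy = Literal["exclude-sample", "exclude-snp", "error"]


class AlleleMismatchError(ValueError):
    """Panel risk allele matches neither allele of the genotype column."""


@dataclass(frozen=True)
class PanelEntry:
    """One risk locus: rsID, its risk allele, and an optional proxy marker."""

    rsid: str
    risk_allele: str
    proxy_rsid: str | None = None
    proxy_r2: float | None = None
    proxy_risk_allele: str | None = None

    def __post_init__(self) -> None:
        if (self.proxy_rsid is None) != (self.proxy_r2 is None):
            raise ValueError(
                f"{self.rsid}: proxy_rsid and proxy_r2 must be given together"
            )
        if self.proxy_r2 is not None and not (0.0 < self.proxy_r2 <= 1.0):
            raise ValueError(f"{self.rsid}: proxy_r2 must be in (0, 1]")
        if self.proxy_rsid is not None and self.proxy_risk_allele is None:
            raise ValueError(
                f"{self.rsid}: proxy_risk_allele must be declared with the proxy "
                "(no automatic LD-phase inference)"
            )


@dataclass(frozen=True)
class SnpPanel:
    """A named set of risk loci from which a GRS is computed."""

    name: str
    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 1:
            raise ValueError("panel must contain at least one SNP")
        rsids = [e.rsid for e in self.entries]
        if len(set(rsids)) != len(rsids):
            raise ValueError(f"duplicate rsIDs in panel {self.name!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def rsids(self) -> list[str]:
        return [e.rsid for e in self.entries]

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "SnpPanel":
        """Load a panel from a TSV with columns rsid, risk_allele and optional
        proxy_rsid, proxy_r2, proxy_risk_allele (empty cells = no proxy)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"rsid", "risk_allele"}
        if not required.issubset(df.columns):
            raise ValueError(f"panel file needs columns {sorted(required)}")
        entries = []
        for _, row in df.iterrows():
            proxy = row.get("proxy_rsid")
            has_proxy = isinstance(proxy, str) and proxy.strip() != ""
            entries.append(
                PanelEntry(
                    rsid=row["rsid"],
                    risk_allele=row["risk_allele"],
                    proxy_rsid=proxy if has_proxy else None,
                    proxy_r2=float(row["proxy_r2"]) if has_proxy else None,
                    proxy_risk_allele=row.get("proxy_risk_allele") if has_proxy else None,
                )
            )
        return cls(name=name or Path(path).stem, entries=tuple(entries))

    @classmethod
    def from_json(cls, path: str | Path) -> "SnpPanel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            name=obj["name"],
            entries=tuple(PanelEntry(**e) for e in obj["entries"]),
        )


@dataclass
class GrsResult:
    """Per-sample GRS with bookkeeping of panel coverage.

    Attributes
    ----------
    score : pd.Series
        Risk-allele count per sample; NaN when the missing-SNP policy
        excluded the sample.
    n_snps_used : pd.Series
        Panel SNPs contributing to each sample's score.
    n_proxied : pd.Series
        How many of those came from a proxy marker.
    panel_name : str
    """

    score: pd.Series
    n_snps_used: pd.Series
    n_proxied: pd.Series
    panel_name: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "score": self.score,
                "n_snps_used": self.n_snps_used,
                "n_proxied": self.n_proxied,
            }
        )


def _oriented_dosage(
    col: pd.Series,
    rsid: str,
    risk_allele: str,
    allele_info: Mapping[str, tuple[str, str]] | None,
) -> pd.Series:
    """Return the dosage counted toward ``risk_allele``.

    ``allele_info`` maps rsid -> (counted_allele, other_allele) for the stored
    column. Without it the column is trusted to already count the risk allele.
    A risk allele matching neither stored allele is an error — no strand flip
    is ever guessed.
    """
    if allele_info is None or rsid not in allele_info:
        return col
    counted, other = allele_info[rsid]
    if risk_allele == counted:
        return col
    if risk_allele == other:
        return 2.0 - col
    raise AlleleMismatchError(
        f"{rsid}: panel risk allele {risk_allele!r} matches neither stored "
        f"allele ({counted!r}/{other!r})"
    )


def apply_proxy(
    dosages: pd.DataFrame,
    entry: PanelEntry,
    allele_info: Mapping[str, tuple[str, str]] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Substitute the proxy marker's dosage where the primary SNP is missing.

    Returns ``(dosage, proxied)``: the risk-allele-oriented dosage for
    ``entry`` with proxy values filled in for samples missing the primary,
    and a boolean flag per sample marking where the proxy was used. Samples
    missing both fall through as NaN (handled by :func:`compute_grs`'s
    missing policy).
    """
    if entry.rsid in dosages.columns:
        primary = _oriented_dosage(
            dosages[entry.rsid], entry.rsid, entry.risk_allele, allele_info
        ).astype(float)
    else:
        primary = pd.Series(np.nan, index=dosages.index)

    proxied = pd.Series(False, index=dosages.index)
    if entry.proxy_rsid is not None and entry.proxy_rsid in dosages.columns:
        proxy = _oriented_dosage(
            dosages[entry.proxy_rsid],
            entry.proxy_rsid,
            entry.proxy_risk_allele,  # type: ignore[arg-type]
            allele_info,
        ).astype(float)
        need = primary.isna() & proxy.notna()
        primary = primary.where(~need, proxy)
        proxied = need
    return primary, proxied


def compute_grs(
    dosages: pd.DataFrame,
    panel: SnpPanel,
    missing_policy: MissingPolicy = "exclude-sample",
    allele_info: Mapping[str, tuple[str, str]] | None = None,
    hard_call: bool = False,
) -> GrsResult:
    """Compute the unweighted risk allele sum score for every sample.

    Parameters
    ----------
    dosages
        Samples × rsIDs dosage matrix, values in [0, 2] or NaN.
    panel
        Risk-locus definitions; proxies are applied automatically.
    missing_policy
        What to do with a sample that has no dosage (primary or proxy) for
        some panel SNP: ``"exclude-sample"`` (default; score becomes NaN,
        mirroring complete-case analysis), ``"exclude-snp"`` (sum over the
        SNPs that are present, recorded in ``n_snps_used``), or ``"error"``.
    allele_info
        Optional rsid -> (counted_allele, other_allele) orientation metadata,
        e.g. from a VCF reader (counted = ALT). Columns without metadata are
        assumed risk-allele-oriented.
    hard_call
        Round dosages to the nearest integer genotype before summing.
    """
    bad = (dosages.select_dtypes("number") < -1e-9) | (
        dosages.select_dtypes("number") > 2 + 1e-9
    )
    if bad.any().any():
        culprit = bad.stack()
        locus, sample = None, None
        for (s, l), v in culprit.items():
            if v:
                sample, locus = s, l
                break
        raise ValueError(f"dosage outside [0, 2] at sample {sample!r}, locus {locus!r}")

    per_snp = {}
    proxied_flags = {}
    for entry in panel.entries:
        if entry.rsid not in dosages.columns and (
            entry.proxy_rsid is None or entry.proxy_rsid not in dosages.columns
        ):
            if missing_policy == "error":
                raise KeyError(
                    f"panel SNP {entry.rsid} absent from genotype data and no "
                    "proxy available"
                )
            per_snp[entry.rsid] = pd.Series(np.nan, index=dosages.index)
            proxied_flags[entry.rsid] = pd.Series(False, index=dosages.index)
            continue
        d, flag = apply_proxy(dosages, entry, allele_info)
        if hard_call:
            d = d.round()
        per_snp[entry.rsid] = d
        proxied_flags[entry.rsid] = flag

    mat = pd.DataFrame(per_snp)
    flags = pd.DataFrame(proxied_flags)
    n_used = mat.notna().sum(axis=1)
    n_proxied = flags.sum(axis=1)

    if missing_policy == "error" and mat.isna().any().any():
        missing_at = mat.isna().any(axis=0)
        raise ValueError(
            f"missing dosages for panel SNPs {list(mat.columns[missing_at])} "
            "under policy 'error'"
        )

    if missing_policy == "exclude-sample":
        score = mat.sum(axis=1, min_count=len(panel))
    else:  # exclude-snp: partial sums with coverage flagged via n_snps_used
        score = mat.sum(axis=1, min_count=1)

    score.name = panel.name
    return GrsResult(
        score=score,
        n_snps_used=n_used.rename("n_snps_used"),
        n_proxied=n_proxied.rename("n_proxied"),
        panel_name=panel.name,
    )


def tertiles(scores: pd.Series | Sequence[float]) -> pd.Series:
    """Assign each sample to a GRS tertile: ``lower`` / ``middle`` / ``highest``.

    Cut points are the empirical order-statistic tertiles; group sizes are as
    equal as ties permit, with a tie block at a boundary going entirely to
    the lower group (deterministic). NaN scores get NaN labels.

    Raises
    ------
    ValueError
        If fewer than 3 distinct score values exist (tertiles undefined).
    """
    s = pd.Series(scores).astype(float)
    valid = s.dropna()
    if valid.nunique() < 3:
        raise ValueError("tertiles undefined: fewer than 3 distinct score values")
    n = len(valid)
    ordered = np.sort(valid.to_numpy())
    # lower order-statistic cuts at ranks ceil(n/3) and ceil(2n/3)
    c1 = ordered[int(np.ceil(n / 3)) - 1]
    c2 = ordered[int(np.ceil(2 * n / 3)) - 1]
    labels = pd.Series(pd.NA, index=s.index, dtype="object")
    labels[s <= c1] = TERTILE_LABELS[0]
    labels[(s > c1) & (s <= c2)] = TERTILE_LABELS[1]
    labels[s > c2] = TERTILE_LABELS[2]
    labels[s.isna()] = pd.NA
    return pd.Series(
        pd.Categorical(labels, categories=list(TERTILE_LABELS), ordered=True),
        index=s.index,
        name="grs_tertile",
    )
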