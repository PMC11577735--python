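"""Gene-signature scoring and population tertile assignment.

Three scoring methods are supported: mean of log2 expression over the
signature's genes (CYTscore, UpperT, LowerT), sum of per-gene z-scores
computed within the cohort (APM), and the difference of two mean-log2
signatures (STRATsig = UpperT - LowerT).  Genes absent from a cohort's
matrix are omitted and reported; scoring fails if fewer than half of a
signature's genes are present unless explicitly overridden.  Tertile
labels are always derived from the full cohort's score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix
from .core import TertileLabels, tertile_split

BUILTIN_FILES = {
    "CYTscore": "cytscore.txt",
    "UpperT": "uppert.txt",
    "LowerT": "lowert.txt",
    "APM": "apm.txt",
}

LABEL_STYLES = {
    "T": ("T1", "T2", "T3"),
    "LoMidHi": ("Lo", "Mid", "Hi"),
}


class SignatureError(ValueError):
    pass


@dataclass
class GeneSignature:
    name: str
    genes: list[str] = field(default_factory=list)
    method: str = "mean_log2"  # mean_log2 | sum_z | difference
    positive: "GeneSignature | None" = None  # for difference signatures
    negative: "GeneSignature | None" = None

    def __post_init__(self) -> None:
        if self.method not in ("mean_log2", "sum_z", "difference"):
            raise SignatureError(f"unknown scoring method {self.method!r}")
        if self.method == "difference":
            if self.positive is None or self.negative is None:
                raise SignatureError(f"difference signature {self.name!r} needs positive and negative components")
        elif not self.genes:
            raise SignatureError(f"signature {self.name!r} has an empty gene list")


@dataclass
class ScoreResult:
    """Per-sample scores plus the genes that could not be used."""

    signature: str
    scores: pd.Series
    used_genes: list[str]
    missing_genes: list[str]


def load_signature_file(path, name: str | None = None, method: str = "mean_log2") -> GeneSignature:
    """Read a gene list, one symbol per line; '#' starts a comment."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return GeneSignature(name=name or str(path), genes=genes, method=method)


def builtin_signature(name: str) -> GeneSignature:
    """One of the shipped signatures: CYTscore, UpperT, LowerT, APM, STRATsig."""
    if name == "STRATsig":
        return GeneSignature(name="STRATsig", method="difference",
                             positive=builtin_signature("UpperT"),
                             negative=builtin_signature("LowerT"))
    if name not in BUILTIN_FILES:
        raise SignatureError(f"unknown built-in signature {name!r}; choose from "
                             f"{sorted(BUILTIN_FILES) + ['STRATsig']}")
    method = "sum_z" if name == "APM" else "mean_log2"
    ref = resources.files("constru.data").joinpath(BUILTIN_FILES[name])
    with resources.as_file(ref) as path:
        return load_signature_file(path, name=name, method=method)


def _present_genes(expr: ExpressionMatrix, signature: GeneSignature,
                   min_fraction: float, allow_partial: bool) -> tuple[list[str], list[str]]:
    present_set = set(expr.feature_ids)
    used = [g for g in signature.genes if g in present_set]
    missing = [g for g in signature.genes if g not in present_set]
    if not used:
        raise SignatureError(
            f"no genes of signature {signature.name!r} present in the matrix; missing: {missing}")
    if not allow_partial and len(used) < min_fraction * len(signature.genes):
        raise SignatureError(
            f"only {len(used)}/{len(signature.genes)} genes of {signature.name!r} present "
            f"(below the {min_fraction:.0%} floor); missing: {missing}")
    return used, missing


def score_mean_log2(expr: ExpressionMatrix, signature: GeneSignature,
                    min_fraction: float = 0.5, allow_partial: bool = False) -> ScoreResult:
    """Per-sample mean of the signature genes' log2 expression values.

    Absent genes are omitted from the mean and listed in the result.
    Multi-probe genes should be collapsed upstream; duplicate rows for a
    signature gene are averaged here as a safeguard.
    """
    used, missing = _present_genes(expr, signature, min_fraction, allow_partial)
    sub = expr.data.loc[expr.data.index.isin(used)]
    sub = sub.groupby(level=0, sort=False).mean()
    scores = sub.mean(axis=0)
    scores.name = signature.name
    return ScoreResult(signature.name, scores, used, missing)


def score_sum_z(expr: ExpressionMatrix, signature: GeneSignature,
                min_fraction: float = 0.5, allow_partial: bool = False) -> ScoreResult:
    """Per-sample sum of within-cohort z-scores of the signature genes.

    z-scores use the population (n) standard deviation across the cohort's
    samples, so every signature's cohort mean is exactly 0.  A signature
    gene with zero variance is an error naming the gene.
    """
    used, missing = _present_genes(expr, signature, min_fraction, allow_partial)
    sub = expr.data.loc[expr.data.index.isin(used)]
    sub = sub.groupby(level=0, sort=False).mean()
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise SignatureError(f"zero-variance signature gene(s): {zero.index.tolist()}")
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    scores = z.sum(axis=0)
    scores.name = signature.name
    return ScoreResult(signature.name, scores, used, missing)


def score_stratsig(expr: ExpressionMatrix,
                   upperT: GeneSignature | None = None,
                   lowerT: GeneSignature | None = None,
                   min_fraction: float = 0.5, allow_partial: bool = False) -> ScoreResult:
    """Stratification signature: mean-log2(UpperT) minus mean-log2(LowerT)."""
    upperT = upperT or builtin_signature("UpperT")
    lowerT = lowerT or builtin_signature("LowerT")
    up = score_mean_log2(expr, upperT, min_fraction, allow_partial)
    lo = score_mean_log2(expr, lowerT, min_fraction, allow_partial)
    scores = up.scores - lo.scores
    scores.name = "STRATsig"
    return ScoreResult("STRATsig", scores, up.used_genes + lo.used_genes,
                       up.missing_genes + lo.missing_genes)


def score_signature(expr: ExpressionMatrix, signature: GeneSignature,
                    min_fraction: float = 0.5, allow_partial: bool = False) -> ScoreResult:
    """Dispatch on the signature's scoring method."""
    if signature.method == "mean_log2":
        return score_mean_log2(expr, signature, min_fraction, allow_partial)
    if signature.method == "sum_z":
        return score_sum_z(expr, signature, min_fraction, allow_partial)
    return score_stratsig(expr, signature.positive, signature.negative,
                          min_fraction, allow_partial)


def assign_score_tertiles(scores, label_style: str = "T") -> TertileLabels:
    """Population tertiles of a per-sample score vector.

    Same split rule and tie handling as the gene-expression tertiles;
    ``label_style`` chooses T1/T2/T3 (stratification signatures) or
    Lo/Mid/Hi (prognostic scores).
    """
    if label_style not in LABEL_STYLES:
        raise SignatureError(f"label_style must be one of {sorted(LABEL_STYLES)}")
    tert = tertile_split(np.asarray(scores, dtype=float))
    mapping = dict(zip(("T1", "T2", "T3"), LABEL_STYLES[label_style]))
    labels = np.array([mapping[t] for t in tert.labels])
    return TertileLabels(labels=labels, boundaries=tert.boundaries)


def score_table(expr: ExpressionMatrix, signatures: list[GeneSignature],
                tertile_styles: dict[str, str] | None = None,
                allow_partial: bool = False) -> pd.DataFrame:
    """Score several signatures and tabulate per-sample scores + tertile labels."""
    tertile_styles = tertile_styles or {}
    out = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"))
    for sig in signatures:
        res = score_signature(expr, sig, allow_partial=allow_partial)
        out[sig.name] = res.scores
        style = tertile_styles.get(sig.name, "LoMidHi" if sig.name == "CYTscore" else "T")
        out[f"{sig.name}_tertile"] = assign_score_tertiles(res.scores.to_numpy(), style).labels
    return out
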