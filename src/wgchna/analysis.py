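"""Downstream module analysis: module-trait correlation, hub genes, exports."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, TraitTable
from .modules import ModuleAssignment

logger = logging.getLogger(__name__)


@dataclass
class ModuleTraitResult:
    """Pearson r and two-sided p per (module eigengene, trait) pair.

    p-values use the Student-t transform t = r sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom.  ``p_adjusted`` carries Benjamini-Hochberg adjusted
    values over all finite entries.
    """

    r: pd.DataFrame  # modules x traits
    p: pd.DataFrame
    p_adjusted: pd.DataFrame


def _pearson_with_p(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r and two-sided t-based p of x against each column of Y."""
    n = x.size
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc @ xc) * (Yc * Yc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc @ Yc) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = np.where(
        np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    )
    return r, p


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    ok = ~np.isnan(flat)
    pv = flat[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    result = np.empty(m)
    result[order] = np.minimum(adjusted, 1.0)
    flat_out = out.ravel()
    flat_out[ok] = result
    return flat_out.reshape(p.shape)


def module_trait_correlation(ME: pd.DataFrame, traits: TraitTable) -> ModuleTraitResult:
    """Correlate every module eigengene with every trait column.

    Zero-variance trait columns yield NaN markers with a warning rather than
    a spurious zero correlation.
    """
    if list(ME.index) != list(traits.sample_ids):
        raise ValueError("eigengene and trait sample sets are not aligned")
    n = ME.shape[0]
    if n < 3:
        raise ValueError("module-trait correlation needs at least 3 samples")
    T = traits.values
    zero_var = T.std(axis=0) == 0
    if zero_var.any():
        bad = [traits.trait_ids[i] for i in np.where(zero_var)[0]]
        logger.warning("zero-variance trait columns reported as NaN: %s", bad)
    r_rows, p_rows = [], []
    for col in ME.columns:
        r, p = _pearson_with_p(ME[col].to_numpy(), T)
        r_rows.append(r)
        p_rows.append(p)
    r = pd.DataFrame(r_rows, index=ME.columns, columns=traits.trait_ids)
    p = pd.DataFrame(p_rows, index=ME.columns, columns=traits.trait_ids)
    padj = pd.DataFrame(
        benjamini_hochberg(p.to_numpy()), index=ME.columns, columns=traits.trait_ids
    )
    return ModuleTraitResult(r, p, padj)


def hub_genes(
    X: ExpressionMatrix,
    assignment: ModuleAssignment,
    ME: pd.DataFrame,
    top_k: int = 10,
) -> pd.DataFrame:
    """Rank genes within each module by module membership kME.

    kME(g, M) is the Pearson correlation of gene g's profile with the
    eigengene of its own module M.  Ranking is by decreasing |kME| with ties
    broken by gene-id order.  Returns a tidy frame with columns
    (module, gene_id, kME, rank), at most ``top_k`` rows per module.
    """
    if list(X.gene_ids) != list(assignment.gene_ids):
        raise ValueError("expression and assignment gene sets differ")
    rows = []
    for lab in sorted(v for v in set(assignment.labels.tolist()) if v != 0):
        me = ME[f"ME{lab}"].to_numpy()
        members = np.where(assignment.labels == lab)[0]
        kme = np.array(
            [np.corrcoef(X.values[i], me)[0, 1] for i in members]
        )
        order = sorted(
            range(members.size), key=lambda i: (-abs(kme[i]), X.gene_ids[members[i]])
        )
        for rank, i in enumerate(order[:top_k], start=1):
            rows.append(
                {
                    "module": lab,
                    "gene_id": X.gene_ids[members[i]],
                    "kME": float(kme[i]),
                    "rank": rank,
                }
            )
    return pd.DataFrame(rows, columns=["module", "gene_id", "kME", "rank"])


def export_module_gene_lists(assignment: ModuleAssignment, out_dir: str | Path) -> Path:
    """Write a GMT file plus one plain-text gene list per non-grey module.

    Returns the GMT path.  Grey genes are excluded by convention.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gmt_path = out_dir / "modules.gmt"
    colors = assignment.colors()
    with open(gmt_path, "w") as gmt:
        for lab in sorted(v for v in set(assignment.labels.tolist()) if v != 0):
            members = [
                g for g, l in zip(assignment.gene_ids, assignment.labels) if l == lab
            ]
            color = colors[int(np.where(assignment.labels == lab)[0][0])]
            gmt.write("\t".join([f"module_{lab}", f"{color} module", *members]) + "\n")
            with open(out_dir / f"module_{lab}_genes.txt", "w") as fh:
                fh.write("\n".join(members) + "\n")
    return gmt_path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: gene list} (round-trip helper)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                sets[fields[0]] = fields[2:]
    return sets
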