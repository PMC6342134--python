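"""Per-sample alpha metrics: abundance, richness, effective species number.

Alpha diversity is the Hill number of order 1, exp(H) with H the Shannon
entropy of the within-sample relative abundances (natural log; the Hill
number is base-invariant).  Empty samples have undefined alpha diversity and
propagate as missing values, never as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .community import CommunityMatrix
from .errors import UndefinedDiversityError, ValidationError


def _as_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1-D species-count vector")
    if (x < 0).any():
        raise ValidationError("negative count in species-count vector")
    return x


def abundance(counts) -> int:
    """Total number of individuals in a sample."""
    return int(_as_counts(counts).sum())


def richness(counts) -> int:
    """Number of morphospecies with at least one individual."""
    return int((_as_counts(counts) > 0).sum())


def effective_species(counts) -> float:
    """Effective number of morphospecies: exp of the Shannon entropy of the
    relative abundances (zero-count species excluded).

    Raises :class:`UndefinedDiversityError` on an empty sample; equals 1 for
    a monoculture and the richness for a perfectly even community.
    """
    x = _as_counts(counts)
    total = x.sum()
    if total == 0:
        raise UndefinedDiversityError("effective_species undefined for an empty sample")
    return float(np.exp(entropy(x[x > 0] / total)))


def alpha_table(cm: CommunityMatrix) -> pd.DataFrame:
    """One row per sample: metadata plus the three alpha metrics.

    ``effective_species`` is NaN (and ``empty_sample`` True) for traps that
    caught nothing.
    """
    rows = []
    mat = cm.counts.to_numpy(dtype=float)
    for i, sid in enumerate(cm.sample_ids):
        x = mat[i]
        ab = int(x.sum())
        rows.append(
            {
                "sample": sid,
                "abundance": ab,
                "richness": int((x > 0).sum()),
                "effective_species": effective_species(x) if ab > 0 else np.nan,
                "empty_sample": ab == 0,
            }
        )
    out = pd.DataFrame(rows).set_index("sample")
    return cm.metadata.join(out)


def alpha_summary(alpha: pd.DataFrame,
                  by: tuple[str, ...] = ("distance_m", "season")) -> pd.DataFrame:
    """Mean +/- SE summaries of the alpha metrics per grouping cell.

    SE = sd / sqrt(n) with n the number of contributing samples (reported);
    empty samples contribute to abundance/richness but not to
    effective_species.
    """
    metrics = ["abundance", "richness", "effective_species"]
    recs = []
    for key, grp in alpha.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(by, key))
        for m in metrics:
            vals = grp[m].dropna().to_numpy(dtype=float)
            n = len(vals)
            rec[f"{m}_mean"] = vals.mean() if n else np.nan
            rec[f"{m}_se"] = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            rec[f"{m}_n"] = n
        recs.append(rec)
    return pd.DataFrame(recs)
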