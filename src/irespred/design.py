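"""Combinatorial TEV-element oligo design and binned activity analysis.

The short C/U-rich TEV IRES element (UACUCCC) is substituted into every
subset of 8 predefined, non-overlapping sites within two 164-nt
background sequences lacking intrinsic IRES activity, giving 2^8 = 256
oligos per background (the empty placement included) and 512 in total.
Each oligo carries a 10-nt barcode (pairwise Hamming distance >= 3) and
constant amplification primers.  Measured activities are analysed in
four bins by number of planted sites (0-1, 2-3, 4-5, 6-8): fraction of
positive oligos per bin, expression of the positives, and a one-way
ANOVA across bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .records import transliterate

TEV_ELEMENT = "UACUCCC"

#: 9-mer spacer used between repeated short IRES elements in earlier
#: designs (TTCTGACAT as RNA); tiled and truncated to 164 nt it forms the
#: synthetic background.
SPACER_9MER = transliterate("TTCTGACAT")
SPACER_BACKGROUND = (SPACER_9MER * 19)[:164]

#: Synthetic stand-in for the 164-nt human beta-globin (HBB) negative
#: control fragment.  This is NOT the native NM_000518 sequence: it is a
#: fixed synthetic placeholder with roughly HBB-like base composition,
#: free of the TEV element.  Substitute the authentic fragment via
#: ``Background(sequence=...)`` when available.
HBB_LIKE_SYNTHETIC = transliterate(
    "GCTGCACGTGGATCCTGAGAACTTCAGGCTCCTGGGCAACGTGCTGGTCTGTGTGCTGGC"
    "CCATCACTTTGGCAAAGAATTCACCCCACCAGTGCAGGCTGCCTATCAGAAAGTGGTGGC"
    "TGGTGTGGCTAATGCCCTGGCCCACAAGTATCACTAAGCTCGCT"
)

DEFAULT_SITE_STARTS = (2, 22, 42, 62, 82, 102, 122, 142)

#: Activity bins over the number of planted sites.
BINS = ((0, 1), (2, 3), (4, 5), (6, 8))

DEFAULT_PRIMER_5 = transliterate("AGGACGGATCGCTTGCCTGT")
DEFAULT_PRIMER_3 = transliterate("CATTGCGTGAACCGAGACCT")


@dataclass(frozen=True)
class Background:
    """A 164-nt background with 8 predefined element sites."""

    name: str
    sequence: str
    site_starts: tuple[int, ...] = DEFAULT_SITE_STARTS

    def __post_init__(self) -> None:
        if len(self.sequence) != 164:
            raise ValueError(f"{self.name}: background must be 164 nt")
        span = len(TEV_ELEMENT)
        starts = sorted(self.site_starts)
        for a, b in zip(starts, starts[1:]):
            if b < a + span:
                raise ValueError(f"{self.name}: overlapping sites {a}, {b}")
        if starts[-1] + span > 164:
            raise ValueError(f"{self.name}: site beyond the variable region")


def default_backgrounds() -> list[Background]:
    return [
        Background("HBB_native", HBB_LIKE_SYNTHETIC),
        Background("spacer_synthetic", SPACER_BACKGROUND),
    ]


@dataclass(frozen=True)
class DesignedOligo:
    id: str
    background: str
    barcode: str
    variable: str
    placement: tuple[int, ...]
    primer_5: str = DEFAULT_PRIMER_5
    primer_3: str = DEFAULT_PRIMER_3

    @property
    def n_sites(self) -> int:
        return len(self.placement)

    @property
    def full_sequence(self) -> str:
        return self.primer_5 + self.barcode + self.variable + self.primer_3


def enumerate_placements(n_sites_available: int = 8) -> list[tuple[int, ...]]:
    """All subsets of the available sites (empty placement included)."""
    if n_sites_available > 16:
        raise ValueError("too many sites to enumerate")
    out: list[tuple[int, ...]] = []
    for mask in range(2**n_sites_available):
        out.append(tuple(i for i in range(n_sites_available) if mask >> i & 1))
    return out


def plant_element(
    background: Background,
    placement: tuple[int, ...],
    element: str = TEV_ELEMENT,
) -> str:
    """Substitute (not insert) the element at each chosen site."""
    seq = list(background.sequence)
    for site in placement:
        start = background.site_starts[site]
        seq[start : start + len(element)] = element
    out = "".join(seq)
    assert len(out) == len(background.sequence)
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def generate_barcodes(
    count: int,
    length: int = 10,
    min_dist: int = 3,
    seed: int = 0,
    forbidden: tuple[str, ...] = (TEV_ELEMENT,),
    max_tries_per_barcode: int = 2000,
) -> list[str]:
    """Greedy rejection sampling of barcodes with pairwise distance >= min_dist.

    Barcodes containing a forbidden substring (by default the planted
    element, to avoid spurious extra sites) are rejected.  Deterministic
    given the seed; raises with the achieved count if the retry budget
    runs out.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    accepted: list[str] = []
    budget = max_tries_per_barcode * count
    tries = 0
    while len(accepted) < count:
        if tries >= budget:
            raise RuntimeError(
                f"barcode search exhausted after {tries} tries; "
                f"achieved {len(accepted)}/{count}"
            )
        tries += 1
        cand = "".join(rng.choice(bases, size=length))
        if any(f in cand for f in forbidden):
            continue
        if all(hamming(cand, b) >= min_dist for b in accepted):
            accepted.append(cand)
    return accepted


def build_design(
    backgrounds: list[Background] | None = None,
    element: str = TEV_ELEMENT,
    seed: int = 0,
    primer_5: str = DEFAULT_PRIMER_5,
    primer_3: str = DEFAULT_PRIMER_3,
) -> list[DesignedOligo]:
    """The full combinatorial design: every placement in every background."""
    if backgrounds is None:
        backgrounds = default_backgrounds()
    placements = enumerate_placements(
        len(backgrounds[0].site_starts) if backgrounds else 8
    )
    total = len(placements) * len(backgrounds)
    barcodes = generate_barcodes(total, seed=seed, forbidden=(element,))
    oligos = []
    i = 0
    for bg in backgrounds:
        for placement in placements:
            oligos.append(
                DesignedOligo(
                    id=f"{bg.name}_{i:04d}",
                    background=bg.name,
                    barcode=barcodes[i],
                    variable=plant_element(bg, placement, element),
                    placement=placement,
                    primer_5=primer_5,
                    primer_3=primer_3,
                )
            )
            i += 1
    return oligos


def design_manifest(oligos: list[DesignedOligo]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [o.id for o in oligos],
            "background": [o.background for o in oligos],
            "placement_mask": [
                sum(1 << s for s in o.placement) for o in oligos
            ],
            "n_sites": [o.n_sites for o in oligos],
            "barcode": [o.barcode for o in oligos],
        }
    )


def write_design(oligos: list[DesignedOligo], out_dir: str | Path) -> None:
    """FASTA of full oligos plus a TSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "design.fa", "w") as fh:
        for o in oligos:
            fh.write(f">{o.id}\n{o.full_sequence}\n")
    design_manifest(oligos).to_csv(out / "manifest.tsv", sep="\t", index=False)


def bin_of(n_sites: int) -> str:
    for lo, hi in BINS:
        if lo <= n_sites <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"site count {n_sites} outside 0..8")


@dataclass
class BinnedAnalysis:
    table: pd.DataFrame
    anova_F: float | None
    anova_p: float | None


def binned_analysis(
    measurements: pd.DataFrame, threshold: float
) -> BinnedAnalysis:
    """Binned fraction-positive and positive-expression analysis.

    ``measurements`` holds one row per observation (replicates pooled as
    separate observations) with columns ``n_sites`` and ``activity``.
    The one-way ANOVA compares activities of positive observations
    across the four bins; it is skipped (None) with a warning when any
    bin has fewer than two positive observations.
    """
    df = measurements.copy()
    df["bin"] = [bin_of(int(k)) for k in df["n_sites"]]
    df["positive"] = df["activity"] > threshold
    rows = []
    positives_per_bin = []
    for lo, hi in BINS:
        label = f"{lo}-{hi}"
        sub = df[df["bin"] == label]
        pos = sub[sub["positive"]]
        positives_per_bin.append(pos["activity"].to_numpy())
        rows.append(
            {
                "bin": label,
                "n_obs": len(sub),
                "n_positive": len(pos),
                "fraction_positive": len(pos) / len(sub) if len(sub) else np.nan,
                "mean_positive_activity": pos["activity"].mean()
                if len(pos)
                else np.nan,
                "median_positive_activity": pos["activity"].median()
                if len(pos)
                else np.nan,
            }
        )
    if all(len(v) >= 2 for v in positives_per_bin):
        F, p = stats.f_oneway(*positives_per_bin)
        anova_F, anova_p = float(F), float(p)
    else:
        warnings.warn("a bin has < 2 positive observations; ANOVA skipped")
        anova_F = anova_p = None
    return BinnedAnalysis(pd.DataFrame(rows), anova_F, anova_p)


def simulate_measurements(
    oligos: list[DesignedOligo],
    per_site_effect: float = 0.5,
    baseline: float = 0.0,
    noise_sd: float = 0.3,
    n_replicates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic measurements with an additive per-site activity effect.

    Emulates the qualitative outcome of the designed-library assay:
    activity grows with the number of planted elements, plus i.i.d.
    Gaussian replicate noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for o in oligos:
        mu = baseline + per_site_effect * o.n_sites
        for rep in range(n_replicates):
            rows.append(
                {
                    "id": o.id,
                    "replicate": rep,
                    "n_sites": o.n_sites,
                    "activity": mu + rng.normal(0, noise_sd),
                }
            )
    return pd.DataFrame(rows)
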