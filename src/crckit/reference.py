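"""Trinucleotide-context conventions and signature reference helpers.

Single-base substitutions are classified into the standard 96 classes:
six pyrimidine-centered substitutions (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 4x4 flanking bases, written ``5'[ref>alt]3'`` (e.g.
``A[C>T]G``).  Substitutions reported on the purine strand are
reverse-complemented onto the pyrimidine strand before classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

PYRIMIDINE_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = ["A", "C", "G", "T"]

#: The 96 substitution classes in the conventional order: substitution-major,
#: then 5' flank, then 3' flank, alphabetical.
CONTEXTS_96: list[str] = [
    f"{five}[{sub}]{three}"
    for sub in PYRIMIDINE_SUBS
    for five in BASES
    for three in BASES
]

CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}

#: The 32 pyrimidine-centered trinucleotides (flank classes used for
#: exome-to-genome abundance normalization).
TRINUCS_32: list[str] = [
    f"{five}{mid}{three}" for mid in ("C", "T") for five in BASES for three in BASES
]


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def classify_substitution(trinuc: str, ref: str, alt: str) -> str:
    """Map a mutation to its 96-class label, pyrimidine-centered.

    ``trinuc`` is the reference trinucleotide around the mutated base; its
    middle base must equal ``ref``.  Purine references are folded onto the
    reverse strand.

    Raises ``ValueError`` on non-ACGT bases or ref == alt.
    """
    trinuc = trinuc.upper()
    ref = ref.upper()
    alt = alt.upper()
    if len(trinuc) != 3 or any(b not in COMPLEMENT for b in trinuc):
        raise ValueError(f"invalid trinucleotide context {trinuc!r}")
    if ref not in COMPLEMENT or alt not in COMPLEMENT or ref == alt:
        raise ValueError(f"invalid substitution {ref!r}>{alt!r}")
    if trinuc[1] != ref:
        raise ValueError(
            f"context middle base {trinuc[1]!r} does not match ref {ref!r}"
        )
    if ref in ("G", "A"):
        trinuc = revcomp(trinuc)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    return f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"


def context_to_trinuc(context: str) -> str:
    """``A[C>T]G`` -> ``ACG`` (the reference pyrimidine trinucleotide)."""
    return context[0] + context[2] + context[6]


def synthetic_signature_reference(
    n_signatures: int = 6, concentration: float = 0.15, seed: int = 20210
) -> pd.DataFrame:
    """Deterministic synthetic 96 x K signature reference matrix.

    A stand-in for a real mutational-signature catalog (e.g. COSMIC v2)
    for simulation and testing: columns are probability distributions over
    the 96 substitution classes, drawn from a sparse Dirichlet so that
    distinct signatures are mutually dissimilar (pairwise cosine typically
    < 0.3 at the default concentration).  Synthetic — the profiles carry
    no biological meaning.
    """
    if n_signatures < 1:
        raise ValueError("n_signatures must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for k in range(n_signatures):
        w = rng.dirichlet(np.full(96, concentration))
        cols[f"Signature {k + 1}"] = w
    return pd.DataFrame(cols, index=pd.Index(CONTEXTS_96, name="context"))


def flat_trinuc_ratio() -> pd.Series:
    """Unit genome/exome abundance ratios for all 32 trinucleotide classes.

    Placeholder normalization (identity); supply measured genome/exome
    trinucleotide counts for real data.
    """
    return pd.Series(1.0, index=pd.Index(TRINUCS_32, name="trinuc"))
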