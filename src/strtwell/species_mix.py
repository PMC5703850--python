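"""Two-species (barnyard) doublet and cross-contamination analysis.

A mixture of cells from two species measures doublet and background rates:
a well whose molecules come from both species at roughly equal ratios held
two cells. To compare similar representations of the two transcriptomes,
analysis is restricted to transcripts with identical names in both species
(case-insensitive). A read belongs unequivocally to a species when it has a
perfect match to a transcript of that species but no match in the other,
even allowing up to 3 mismatches. Molecules are distinct per-position UMIs
with singletons excluded, as in the main pipeline.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping as TMapping

import pandas as pd

from .alignment import NaiveAligner, ReadAlignment
from .plate_layout import WellAddress
from .read_processing import ProcessedRead

logger = logging.getLogger(__name__)

DEFAULT_MINOR_FRACTION = 0.2
DEFAULT_MIN_TOTAL = 100


@dataclass
class JointSpeciesReference:
    """Per-species transcript sequences restricted to shared names.

    ``transcripts_a``/``transcripts_b`` map the (lower-cased) shared gene
    name to the transcript sequence in each species; the two name sets are
    identical by construction.
    """

    species_a: str
    species_b: str
    transcripts_a: dict[str, str]
    transcripts_b: dict[str, str]
    _aligner_a: NaiveAligner | None = field(default=None, repr=False)
    _aligner_b: NaiveAligner | None = field(default=None, repr=False)

    @property
    def shared_names(self) -> list[str]:
        return sorted(self.transcripts_a)

    def aligners(self, max_mismatches: int = 3) -> tuple[NaiveAligner, NaiveAligner]:
        if self._aligner_a is None:
            self._aligner_a = NaiveAligner(
                self.transcripts_a, max_mismatches, max_hits=10**9
            )
            self._aligner_b = NaiveAligner(
                self.transcripts_b, max_mismatches, max_hits=10**9
            )
        return self._aligner_a, self._aligner_b


def build_joint_reference(
    ref_a: TMapping[str, str],
    ref_b: TMapping[str, str],
    species_a: str = "A",
    species_b: str = "B",
) -> JointSpeciesReference:
    """Restrict two name->sequence transcript sets to shared names.

    Name matching disregards upper/lower case; an empty intersection is an
    error (the species pair cannot be compared).
    """
    lower_a = {name.lower(): seq for name, seq in ref_a.items()}
    lower_b = {name.lower(): seq for name, seq in ref_b.items()}
    shared = sorted(set(lower_a) & set(lower_b))
    if not shared:
        raise ValueError("no transcript names shared between the two species")
    return JointSpeciesReference(
        species_a,
        species_b,
        {n: lower_a[n] for n in shared},
        {n: lower_b[n] for n in shared},
    )


def classify_read_species(
    payload: str,
    joint_reference: JointSpeciesReference,
    max_mismatches: int = 3,
) -> str | None:
    """Unequivocal species call for one read payload.

    Returns the species label iff the read matches that species' transcripts
    perfectly and has no hit at all (within ``max_mismatches``) in the other
    species; otherwise None. Symmetric in the two species.
    """
    aligner_a, aligner_b = joint_reference.aligners(max_mismatches)
    hits_a = aligner_a.align(payload)
    hits_b = aligner_b.align(payload)
    perfect_a = any(m.mismatches == 0 for m in hits_a)
    perfect_b = any(m.mismatches == 0 for m in hits_b)
    if perfect_a and not hits_b:
        return joint_reference.species_a
    if perfect_b and not hits_a:
        return joint_reference.species_b
    return None


def count_species_molecules(
    reads: Iterable[ReadAlignment | ProcessedRead],
    joint_reference: JointSpeciesReference,
    max_mismatches: int = 3,
    min_reads_per_umi: int = 2,
) -> pd.DataFrame:
    """Per-well species molecule counts from classified reads.

    Accepts processed reads (payload + well + UMI); for each species-
    assignable read the molecule key is its best perfect-match position in
    the assigned species. Molecules are distinct UMIs per position with
    singleton-UMI exclusion. Returns a DataFrame indexed by well string with
    columns molecules_A / molecules_B (named after the species).
    """
    aligner_a, aligner_b = joint_reference.aligners(max_mismatches)
    # well -> species -> (transcript, pos, strand) -> umi -> reads
    tallies: dict[WellAddress, dict[str, dict[tuple, Counter]]] = defaultdict(
        lambda: {joint_reference.species_a: {}, joint_reference.species_b: {}}
    )
    for read in reads:
        payload = read.payload
        if not payload or read.well is None:
            continue
        species = classify_read_species(payload, joint_reference, max_mismatches)
        if species is None:
            continue
        aligner = aligner_a if species == joint_reference.species_a else aligner_b
        perfect = [m for m in aligner.align(payload) if m.mismatches == 0]
        m = perfect[0]
        key = (m.chrom, m.five_prime_pos, m.strand)
        tallies[read.well][species].setdefault(key, Counter())[read.umi] += 1
    rows = {}
    for well in sorted(tallies):
        row = {}
        for species in (joint_reference.species_a, joint_reference.species_b):
            row[f"molecules_{species}"] = sum(
                sum(1 for c in umis.values() if c >= min_reads_per_umi)
                for umis in tallies[well][species].values()
            )
        rows[str(well)] = row
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)


def call_wells(
    counts: pd.DataFrame,
    minor_fraction_threshold: float = DEFAULT_MINOR_FRACTION,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> pd.DataFrame:
    """Label each well empty / singlet / doublet from species molecule counts.

    A well is empty below ``min_total`` molecules; a doublet when the minor
    species contributes at least ``minor_fraction_threshold`` of molecules
    ("roughly equal ratios"); otherwise a singlet of the majority species.
    The thresholds are reported in the output attrs since any quoted doublet
    percentage is threshold-dependent.
    """
    if not 0 < minor_fraction_threshold <= 0.5:
        raise ValueError("minor_fraction_threshold must be in (0, 0.5]")
    a_col, b_col = counts.columns[0], counts.columns[1]
    species_a = a_col.removeprefix("molecules_")
    species_b = b_col.removeprefix("molecules_")
    labels = []
    for _, row in counts.iterrows():
        a, b = int(row[a_col]), int(row[b_col])
        total = a + b
        if total < min_total:
            labels.append("empty")
        elif min(a, b) / total >= minor_fraction_threshold:
            labels.append("doublet")
        else:
            labels.append(f"singlet_{species_a if a >= b else species_b}")
    out = counts.copy()
    out["label"] = labels
    out.attrs["minor_fraction_threshold"] = minor_fraction_threshold
    out.attrs["min_total"] = min_total
    return out


def doublet_rate(called: pd.DataFrame, include_empty: bool = False) -> float:
    """Fraction of (non-empty) wells labeled doublet."""
    labels = called["label"]
    if not include_empty:
        labels = labels[labels != "empty"]
    if len(labels) == 0:
        return float("nan")
    return float((labels == "doublet").mean())


def background_stats(called: pd.DataFrame) -> dict[str, float]:
    """Other-species molecules in singlet wells (ambient contamination).

    Returns mean/median/max of the minor-species molecule count restricted
    to singlet-labeled wells; empty dict with a warning when there are none.
    """
    singlets = called[called["label"].str.startswith("singlet")]
    if singlets.empty:
        logger.warning("no singlet wells; background statistics undefined")
        return {}
    a_col, b_col = called.columns[0], called.columns[1]
    minor = singlets[[a_col, b_col]].min(axis=1)
    return {
        "n_singlets": int(len(singlets)),
        "mean_background": float(minor.mean()),
        "median_background": float(minor.median()),
        "max_background": float(minor.max()),
    }


def write_barnyard_tables(called: pd.DataFrame, prefix: str) -> None:
    """Per-well TSV plus summary TSV (doublet rate, background stats)."""
    called.to_csv(f"{prefix}.wells.tsv", sep="\t", index_label="well")
    stats = background_stats(called)
    with open(f"{prefix}.summary.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"doublet_rate\t{doublet_rate(called)}\n")
        fh.write(
            "minor_fraction_threshold\t"
            f"{called.attrs.get('minor_fraction_threshold', '')}\n"
        )
        fh.write(f"min_total\t{called.attrs.get('min_total', '')}\n")
        for k, v in stats.items():
            fh.write(f"{k}\t{v}\n")
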