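"""Packaged fixtures: the T. spiralis U12 candidate table and consensus PWMs.

The candidate table carries, for each of the 16 EST-supported U12 intron
candidates reported for *Trichinella spiralis*: the three exonic bases either
side of the intron, the printed 5'- and 3'-terminal intron fragments, the
intron length, the probability-ratio method flag (B), the 5'-rule flag (R),
and the relationship of the intron to its *C. elegans* orthologue.  The
interior of each intron was not printed, so reconstructed sequences carry N
for the unprinted stretch.

The matrix files are consensus-derived frequency matrices in the package's
flat format, one per (site type, intron class) pair, built from the
synthetic generator's consensus motifs; they let the whole pipeline run
offline.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .intron_discovery import IntronCandidate, SpeciesPwmSet
from .matrices import (FrequencyMatrix, IntronClass, SiteType, load_matrix,
                       to_pwm)


def _data_path(*parts: str):
    return resources.files("u12scan").joinpath("data", *parts)


def load_table1() -> pd.DataFrame:
    """The 16-row T. spiralis U12 candidate table as a DataFrame."""
    with resources.as_file(_data_path("table1_tspiralis.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str).astype(
            {"intron_length": int})


def table1_intron_candidates() -> list[IntronCandidate]:
    """The candidate table as IntronCandidate records.

    Only the terminal fragments were printed; the interior of each intron is
    filled with N so that lengths, termini, and both terminal windows are
    faithful while the middle is explicitly unknown.
    """
    out = []
    for rec in load_table1().itertuples():
        n_fill = rec.intron_length - len(rec.intron_5p) - len(rec.intron_3p)
        seq = rec.intron_5p + "N" * max(0, n_fill) + rec.intron_3p
        out.append(IntronCandidate(
            contig_id="Tspiralis", start=0, end=rec.intron_length,
            sequence=seq, donor_dinuc=seq[:2], acceptor_dinuc=seq[-2:],
            exon5_context=rec.exon5, exon3_context=rec.exon3,
            est_id=rec.est_id))
    return out


def fixture_matrix_dir() -> Path:
    with resources.as_file(_data_path("matrices")) as p:
        return Path(p)


def load_fixture_matrices(directory: str | Path | None = None
                          ) -> dict[tuple[SiteType, IntronClass],
                                    FrequencyMatrix]:
    """Load all packaged (or user-supplied) matrix flat files."""
    directory = Path(directory) if directory else fixture_matrix_dir()
    out = {}
    for path in sorted(directory.glob("*.txt")):
        m = load_matrix(path)
        out[(m.site_type, m.intron_class)] = m
    if not out:
        raise FileNotFoundError(f"no matrix files in {directory}")
    return out


def fixture_pwm_sets(freqs=None, prob_floor: float = 1e-4
                     ) -> list[SpeciesPwmSet]:
    """Splice-site resolution PWM sets from the packaged matrices.

    One set carrying the 5' and 3' PWMs of every intron class, so junction
    resolution considers the consensus of each class.
    """
    freqs = freqs or load_fixture_matrices()
    five = [to_pwm(m, prob_floor) for (site, _), m in sorted(freqs.items())
            if site == SiteType.FIVE_PRIME]
    three = [to_pwm(m, prob_floor) for (site, _), m in sorted(freqs.items())
             if site == SiteType.THREE_PRIME]
    return [SpeciesPwmSet("fixture", five, three)]
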