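"""Bundled reference tables for the date-palm chloroplast genome.

Two small published summaries ship with the package so that the codon
statistics and genotype arithmetic can be exercised without any external
download: the genome-wide codon usage counts (with the printed RSCU values
and anticodon assignments) and the coding-region intravarietal SNP table
(major/minor genotypes with read counts and percentages).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _data_path(fname: str):
    return resources.files("plastidkit.data").joinpath(fname)


def codon_usage() -> pd.DataFrame:
    """Published codon usage of the date-palm chloroplast genome: one row
    per codon (RNA alphabet) with amino acid, count, printed RSCU and, where
    present, the cognate tRNA."""
    with _data_path("date_palm_cp_codon_usage.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["trna"] = df["trna"].fillna("") if "trna" in df else ""
    return df


def codon_counts() -> dict[str, int]:
    """Codon → count mapping (RNA alphabet) from :func:`codon_usage`."""
    df = codon_usage()
    return dict(zip(df["codon"], df["count"].astype(int)))


def coding_intrasnps() -> pd.DataFrame:
    """Published coding-region intravarietal SNPs: gene, major/minor bases,
    codons, read counts, percentages, strand, CDS and genome positions, and
    a flag for sites whose major/minor assignment is swapped in oil palm.

    One site shares its codon with the preceding row and is printed without
    its own counts; its count columns are NaN here, exactly as published.
    """
    with _data_path("date_palm_cp_coding_intrasnps.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


#: The small inversion in the psaB coding region of date palm
#: (genome coordinates 38,667-38,729): a 63-bp hairpin whose perfect
#: inverted-repeat stem is 13 bp and loop 37 bp.
PSAB_SMALL_INVERSION = (
    "ATCGAACCCATATGAAGTCTTACCATGAGCGGATTGTATCCATTGGGCAAATATGGGTTCGAT"
)

#: The orthologous span in Acorus americanus, which carries three stem
#: substitutions and folds into a much less stable hairpin.
PSAB_SMALL_INVERSION_ACORUS = (
    "ATCAAACCCATATAAAGTCTTACCATGAGCGGATTGTATCCACTGGGCAAATATAGGTTCAAT"
)

#: Published quadripartite region lengths of the date-palm chloroplast
#: genome (bp): LSC, SSC, and one IR copy.
DATE_PALM_REGION_LENGTHS = {"lsc": 86198, "ssc": 17712, "ir": 27276}
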