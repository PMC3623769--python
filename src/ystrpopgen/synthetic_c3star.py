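"""Synthetic stand-in for the 14 Ecuadorian C3* haplotypes.

The per-sample genotypes of the 14 C3* chromosomes live in a supplementary
table that was never publicly deposited, but their mutational configuration
on the network panel (minimal-haplotype loci plus DYS439, DYS389II coded as
DYS389II-DYS389I) is fully described in the survey's text:

* H7 — eight identical Kichwa chromosomes (also matching Koryak samples);
* H162 — two Kichwa chromosomes one step from H7 at DYS391;
* H163 — one Kichwa chromosome two steps from H7 (DYS391 and DYS439);
* three identical Waorani chromosomes 10-16 mutational steps from the
  Kichwa cluster.

This module reconstructs that configuration SYNTHETICALLY: multiplicities
and within-cluster step differences are exact; absolute repeat counts follow
the common East Asian C3* modal haplotype. The direct Waorani-Kichwa
difference is not printed: the 10-16 figure refers to path lengths through
the published 167-haplotype Asian/American network (paths run from the
Waorani node through Asian haplotypes and quasi-medians), and a network path
can only be at least as long as the direct repeat difference. The direct
difference used here is 8 steps spread over five loci, the value jointly
consistent with that upper bound and with the published coalescence scale of
the sample (about 200 generations at the panel's total mutation rate of
about 0.02 per generation, i.e. roughly eight expected mutations between the
cluster ancestors). Analyses that depend only on the mutational
configuration (TMRCA estimation, network topology) are faithful to the
described data; absolute allele labels are not.
"""

__all__ = ["C3STAR_MARKERS", "c3star_sample", "c3star_profiles", "c3star_labels"]

#: Network panel order; DYS389II here means the differenced coding
#: (second locus alone).
C3STAR_MARKERS = (
    "DYS19",
    "DYS389I",
    "DYS389II",
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
    "DYS439",
)

_H7 = (16, 13, 16, 25, 10, 11, 13, 10)  # Kichwa modal, 8 copies
_H162 = (16, 13, 16, 25, 11, 11, 13, 10)  # +1 at DYS391, 2 copies
_H163 = (16, 13, 16, 25, 11, 11, 13, 11)  # +1 at DYS391 and DYS439, 1 copy
# Waorani haplotype: 8 steps from H7 (DYS19 +1, DYS390 -2, DYS391 +2,
# DYS392 +1, DYS439 +2), 3 copies
_WAO = (17, 13, 16, 23, 12, 12, 13, 12)


def c3star_sample():
    """The 14 stand-in profiles with population labels, as (profiles, labels)."""
    profiles = []
    labels = []
    for hap, mult, pop in (
        (_H7, 8, "Kichwa"),
        (_H162, 2, "Kichwa"),
        (_H163, 1, "Kichwa"),
        (_WAO, 3, "Waorani"),
    ):
        for _ in range(mult):
            profiles.append(dict(zip(C3STAR_MARKERS, hap)))
            labels.append(pop)
    return profiles, labels


def c3star_profiles():
    return c3star_sample()[0]


def c3star_labels():
    return c3star_sample()[1]
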