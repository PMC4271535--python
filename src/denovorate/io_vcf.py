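"""VCF v4.2 subset reader/writer for multi-sample site calls.

Only what the filters consume is represented: CHROM, POS, REF, ALT, QUAL,
the LowQual FILTER flag, and per-sample GT:AD:DP. Variant (alternate-base)
sites are written; multiallelic records read from external files are kept
but flagged so downstream counting can exclude them. Parsing and writing go
through pysam.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator

import numpy as np
import pysam

from .genotyper import HET, HOMALT, HOMREF, UNDEF, SiteCall

log = logging.getLogger(__name__)

_GT_TO_TUPLE = {HOMREF: (0, 0), HET: (0, 1), HOMALT: (1, 1),
                UNDEF: (None, None)}


def _header(samples: list[str], contigs: Iterable[str]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.add_line('##source=denovorate')
    for c in contigs:
        h.contigs.add(c)
    h.filters.add("LowQual", None, None, "Low quality site")
    h.formats.add("GT", 1, "String", "Genotype")
    h.formats.add("AD", "R", "Integer",
                  "Allelic depths for the ref and alt alleles")
    h.formats.add("DP", 1, "Integer", "Total read depth")
    for s in samples:
        h.add_sample(s)
    return h


def write_vcf(calls: Iterable[SiteCall], path: str, samples: list[str],
              contigs: Iterable[str] | None = None) -> int:
    """Write variant SiteCalls to ``path``; returns the record count.

    Calls without an alternate base are skipped (the file carries variant
    records only, as a caller would emit)."""
    calls = list(calls)
    if contigs is None:
        seen = []
        for c in calls:
            if c.chrom not in seen:
                seen.append(c.chrom)
        contigs = seen or ["chr01"]
    header = _header(samples, contigs)
    n = 0
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in calls:
            if call.alt is None:
                continue
            rec = out.new_record(
                contig=call.chrom, start=call.pos - 1, stop=call.pos,
                alleles=(call.ref, call.alt), qual=round(call.site_qual, 2))
            rec.filter.add("LowQual" if call.lowqual else "PASS")
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = _GT_TO_TUPLE[int(call.genotypes[i])]
                rec.samples[s]["AD"] = (int(call.ref_ad[i]), int(call.alt_ad[i]))
                rec.samples[s]["DP"] = int(call.depth[i])
            out.write(rec)
            n += 1
    return n


def _genotype_code(gt_tuple) -> int:
    if gt_tuple is None or any(a is None for a in gt_tuple):
        return UNDEF
    s = sum(gt_tuple)
    return {0: HOMREF, 1: HET, 2: HOMALT}.get(s, HET)


def read_vcf(path: str) -> Iterator[SiteCall]:
    """Stream SiteCalls from a VCF with GT:AD:DP sample fields.

    Records missing AD or DP are skipped with a logged warning; multiallelic
    records are yielded with the multiallelic flag set (downstream counting
    excludes them)."""
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            multi = len(alts) > 1
            alt = alts[0] if alts else None
            n = len(samples)
            gts = np.full(n, UNDEF, dtype=np.int8)
            ref_ad = np.zeros(n, dtype=np.int64)
            alt_ad = np.zeros(n, dtype=np.int64)
            depth = np.zeros(n, dtype=np.int64)
            ok = True
            for i, s in enumerate(samples):
                fmt = rec.samples[s]
                if "AD" not in fmt or "DP" not in fmt or fmt["DP"] is None:
                    log.warning("record %s:%d sample %s missing AD/DP; "
                                "record skipped", rec.chrom, rec.pos, s)
                    ok = False
                    break
                gts[i] = _genotype_code(fmt.get("GT"))
                ad = fmt["AD"]
                ref_ad[i] = ad[0] if ad and ad[0] is not None else 0
                alt_ad[i] = (ad[1] if ad and len(ad) > 1 and ad[1] is not None
                             else 0)
                depth[i] = fmt["DP"]
            if not ok:
                continue
            lowqual = "LowQual" in rec.filter
            yield SiteCall(rec.chrom, rec.pos, rec.ref, alt, gts, ref_ad,
                           alt_ad, depth, float(rec.qual or 0.0), lowqual,
                           multi)
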