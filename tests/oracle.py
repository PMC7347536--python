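"""Independent straight-line re-implementation of the filter rules.

Deliberately written as one flat function over plain attribute reads, with no
imports from :mod:`tmbkit.filters`, so it can serve as an oracle for the
cascade: any divergence between the two implementations is a bug in one of
them.
"""


def oracle_failed_rules(call, pon_entries, cfg, matched_normal_afs=None):
    """Return the set of failed rule codes for one call.

    ``pon_entries`` maps (chrom,pos,ref,alt) -> list of Af_normal floats;
    ``matched_normal_afs`` (paired mode) is an extra map merged on top.
    """
    failed = set()

    c = call.variant_class
    if c in ("snv", "indel", "frameshift", "start_stop"):
        pass
    elif c == "synonymous":
        if not cfg.include_synonymous:
            failed.add("class")
    elif c == "splice":
        if abs(call.splice_offset) > cfg.splice_window_bp:
            failed.add("splice")
    else:  # "other" and anything unrecognized
        failed.add("class")

    if call.population_maf is not None and call.population_maf >= cfg.maf_threshold:
        failed.add("maf")

    if call.in_dbsnp and not call.in_cosmic:
        failed.add("dbsnp")

    if call.alt_depth < cfg.min_alt_reads:
        failed.add("support")
    if call.vaf < cfg.min_vaf:
        failed.add("support")

    if call.mq_pass_fraction < cfg.min_mq_pass_fraction:
        failed.add("mq")

    afs = list(pon_entries.get(call.key, []))
    if matched_normal_afs is not None:
        afs = afs + list(matched_normal_afs.get(call.key, []))
    for af in afs:
        if call.vaf / af <= cfg.pon_ratio:
            failed.add("pon")
            break

    return failed
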