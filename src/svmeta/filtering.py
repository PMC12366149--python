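"""SV-call filtering: size, type, autosome, region and genotype predicates."""

from __future__ import annotations

from .types import AUTOSOMES, FilterConfig, SVCall


def _passes(call: SVCall, config: FilterConfig) -> bool:
    if call.svlen < config.min_svlen:
        return False
    if call.svtype not in config.allowed_types:
        return False
    if config.autosomes_only and call.chrom not in AUTOSOMES:
        return False
    if config.require_nonref_genotype and not call.genotype.is_nonref:
        return False
    if config.require_filter_pass and not call.filter_pass:
        return False
    if config.include_regions is not None and not config.include_regions.contains_call(
        call.chrom, call.pos, call.end
    ):
        return False
    return True


def filter_sv_calls(calls: list[SVCall], config: FilterConfig) -> list[SVCall]:
    """Return the subset of ``calls`` satisfying every configured predicate.

    Order is preserved; the default configuration keeps autosomal DEL/INS
    calls of length >= 50 bp. Filtering is idempotent.
    """
    return [c for c in calls if _passes(c, config)]
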