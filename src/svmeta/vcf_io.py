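"""Reading caller VCF dialects and writing the scored consensus VCF.

Reading goes through :mod:`pysam`; writing emits VCF 4.2 text directly so
the output contract (QUAL printed with four decimals, stable INFO key
order) is byte-reproducible.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import pysam

from . import __version__
from .dialects import CallerDialect, DialectRegistry, MetricSpec
from .types import ConsensusCall, Genotype, SVCall, SVType, normalize_chrom


class VCFFormatError(ValueError):
    pass


def _as_float(value) -> Optional[float]:
    """Coerce a pysam INFO/FORMAT value to float, or None when unparseable."""
    if value is None:
        return None
    if isinstance(value, bool):
        return 1.0 if value else 0.0
    if isinstance(value, (tuple, list)):
        if not value:
            return None
        value = value[-1]  # alt-allele entry of Number=R/A fields
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return out if out == out else None  # NaN in file -> missing


def _genotype_of(record) -> Genotype:
    if not record.samples:
        return Genotype.missing
    sample = record.samples[0]
    gt = sample.get("GT")
    if gt is None or any(a is None for a in gt):
        return Genotype.missing
    alts = sum(1 for a in gt if a > 0)
    if alts == 0:
        return Genotype.hom_ref
    if alts == len(gt):
        return Genotype.hom_alt
    return Genotype.het


def _svtype_token(record) -> Optional[str]:
    token = record.info.get("SVTYPE")
    if isinstance(token, (tuple, list)):
        token = token[0] if token else None
    if token is None and record.alts:
        alt = record.alts[0]
        if alt and alt.startswith("<") and alt.endswith(">"):
            token = alt[1:-1].split(":")[0]
    return token


def _extract_metric(record, spec: MetricSpec) -> Optional[float]:
    if spec.source == "QUAL":
        return _as_float(record.qual)
    if spec.source == "INFO":
        header_info = record.header.info.get(spec.vcf_field)
        if header_info is None:
            return None  # field not declared in this VCF
        if header_info.type == "Flag":
            return 1.0 if spec.vcf_field in record.info else 0.0
        return _as_float(record.info.get(spec.vcf_field))
    # FORMAT: first sample
    if not record.samples:
        return None
    try:
        return _as_float(record.samples[0].get(spec.vcf_field))
    except (KeyError, ValueError):
        return None


def parse_caller_vcf(
    path: str | os.PathLike,
    dialect: CallerDialect,
    registry: Optional[DialectRegistry] = None,
) -> list[SVCall]:
    """Parse one caller's VCF into harmonized :class:`SVCall` records.

    Duplications are folded into the insertion class at parse time; negative
    deletion SVLEN values are absolute-valued; records whose SV type the
    dialect does not recognize are skipped. Unparseable metric values are
    recorded as missing, never as 0.
    """
    try:
        vcf = pysam.VariantFile(os.fspath(path))
    except (ValueError, OSError) as exc:
        raise VCFFormatError(f"cannot read VCF {path}: {exc}") from exc

    calls: list[SVCall] = []
    with vcf:
        for i, record in enumerate(vcf):
            token = _svtype_token(record)
            if token is None or token not in dialect.svtype_map:
                continue
            svtype = dialect.svtype_map[token]

            svlen_raw = record.info.get("SVLEN") if "SVLEN" in record.header.info else None
            if isinstance(svlen_raw, (tuple, list)):
                svlen_raw = svlen_raw[0] if svlen_raw else None
            pos = record.pos  # 1-based
            # pysam's stop reflects INFO END only when SVLEN is absent
            # (htslib recomputes the record span from SVLEN otherwise), so
            # deletion ends are anchored on pos + svlen - 1 when SVLEN is
            # given and on END otherwise.
            if svlen_raw is not None:
                svlen = abs(int(svlen_raw))
                end = pos + svlen - 1 if svtype is SVType.DEL else pos
            elif svtype is SVType.DEL and record.stop > pos:
                end = record.stop
                svlen = end - pos + 1
            else:
                continue  # no usable length
            if svlen < 1:
                continue

            specs = (
                registry.metric_specs(dialect.caller, svtype)
                if registry is not None
                else dialect.specs_for(svtype)
            )
            metrics = {spec.name: _extract_metric(record, spec) for spec in specs}

            filters = list(record.filter.keys())
            calls.append(
                SVCall(
                    id=record.id or f"{dialect.caller}_{i}",
                    caller=dialect.caller,
                    chrom=record.chrom,
                    pos=pos,
                    end=end,
                    svtype=svtype,
                    svlen=svlen,
                    genotype=_genotype_of(record),
                    precise="IMPRECISE" not in record.info,
                    metrics=metrics,
                    filter_pass=(not filters) or filters == ["PASS"],
                )
            )
    return calls


_GENERIC_DIALECT = CallerDialect(caller="generic")


def parse_sv_vcf(path: str | os.PathLike, caller: str = "truth") -> list[SVCall]:
    """Parse a plain SV VCF (e.g. a truth set) without any metric dialect."""
    dialect = CallerDialect(caller=caller)
    return parse_caller_vcf(path, dialect)


# ---------------------------------------------------------------------------
# writing


def _vcf_header(
    contigs: Sequence[str],
    info_lines: Sequence[str],
    format_lines: Sequence[str] = (),
    extra: Sequence[str] = (),
    sample: Optional[str] = None,
) -> list[str]:
    lines = ["##fileformat=VCFv4.2", f"##source=svmeta-{__version__}"]
    lines.extend(extra)
    lines.extend(f"##contig=<ID={c}>" for c in contigs)
    lines.extend(info_lines)
    lines.extend(format_lines)
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if sample:
        cols += f"\tFORMAT\t{sample}"
    lines.append(cols)
    return lines


_CONSENSUS_INFO = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="1-based inclusive end">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length in bp">',
    '##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Number of distinct supporting callers">',
    '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting caller names">',
    '##INFO=<ID=MEMBER_IDS,Number=.,Type=String,Description="caller:id of every contributing call">',
]


def write_consensus_vcf(
    consensus: Iterable[ConsensusCall],
    path: str | os.PathLike,
    extra_header: Sequence[str] = (),
) -> None:
    """Write scored consensus calls as a probability-ranked VCF 4.2 file.

    QUAL carries the model's TP probability (four decimals); INFO lists the
    contributing caller-local record IDs for lookup in the standalone VCFs.
    """
    consensus = sorted(consensus, key=lambda c: (c.chrom, c.pos, c.end, c.svtype.value))
    for call in consensus:
        if call.probability is not None and not (0.0 <= call.probability <= 1.0):
            raise ValueError(
                f"consensus call {call.id} has probability {call.probability} "
                "outside [0, 1]"
            )
    contigs = sorted({c.chrom for c in consensus}, key=_chrom_sort_key)
    lines = _vcf_header(contigs, _CONSENSUS_INFO, extra=list(extra_header))
    for call in consensus:
        qual = "." if call.probability is None else f"{call.probability:.4f}"
        member_ids = ",".join(f"{caller}:{mid}" for caller, mid in sorted(call.members))
        info = (
            f"SVTYPE={call.svtype.value};END={call.end};SVLEN={call.svlen};"
            f"SUPP={call.supp};CALLERS={','.join(call.callers)};"
            f"MEMBER_IDS={member_ids}"
        )
        alt = f"<{call.svtype.value}>"
        lines.append(
            f"{call.chrom}\t{call.pos}\t{call.id}\tN\t{alt}\t{qual}\tPASS\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def parse_consensus_vcf(path: str | os.PathLike) -> list[ConsensusCall]:
    """Read back a consensus VCF written by :func:`write_consensus_vcf`."""
    out: list[ConsensusCall] = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for record in vcf:
            members = []
            raw = record.info.get("MEMBER_IDS", ())
            if isinstance(raw, str):
                raw = (raw,)
            for token in raw:
                caller, _, mid = token.partition(":")
                members.append((caller, mid))
            svtype = SVType(_svtype_token(record))
            svlen = abs(int(record.info["SVLEN"]))
            out.append(
                ConsensusCall(
                    id=record.id,
                    chrom=record.chrom,
                    pos=record.pos,
                    end=record.pos + svlen - 1 if svtype is SVType.DEL else record.pos,
                    svtype=svtype,
                    svlen=svlen,
                    members=members,
                    probability=record.qual,
                )
            )
    return out


def _chrom_sort_key(chrom: str):
    c = normalize_chrom(chrom)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def write_caller_vcf(
    path: str | os.PathLike,
    calls: Sequence[SVCall],
    registry: DialectRegistry,
    contigs: Sequence[str],
    dup_ids: frozenset[str] | set[str] = frozenset(),
) -> None:
    """Serialize simulated/harmonized calls in a caller's dialect.

    Each metric is written back to the VCF field its :class:`MetricSpec`
    names (INFO, FORMAT or QUAL); the PRECISE/IMPRECISE status is written as
    the conventional INFO flags. Missing metric values are omitted.
    Insertion calls whose ID is listed in ``dup_ids`` are emitted with the
    DUP type token (a duplication dialect, folded back to INS at parse
    time). A caller without a registered dialect (e.g. a truth set) is
    written with no metric fields.
    """

    def _specs_of(caller: str, svtype: SVType) -> tuple[MetricSpec, ...]:
        try:
            return registry.metric_specs(caller, svtype)
        except KeyError:
            return ()

    if not calls:
        caller_specs: tuple[MetricSpec, ...] = ()
    else:
        caller = calls[0].caller
        seen: dict[str, MetricSpec] = {}
        for svt in (SVType.DEL, SVType.INS):
            for spec in _specs_of(caller, svt):
                seen.setdefault(spec.name, spec)
        caller_specs = tuple(seen.values())

    info_fields: dict[str, str] = {}
    format_fields: dict[str, str] = {}
    for spec in caller_specs:
        if spec.source == "INFO" and spec.vcf_field not in ("PRECISE", "IMPRECISE"):
            info_fields[spec.vcf_field] = "Float"
        elif spec.source == "FORMAT":
            format_fields[spec.vcf_field] = "Float"

    info_lines = [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Precise breakpoints">',
        '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoints">',
    ]
    info_lines += [
        f'##INFO=<ID={f},Number=1,Type={t},Description="caller metric">'
        for f, t in sorted(info_fields.items())
    ]
    info_lines.append('##FILTER=<ID=LowQual,Description="Below caller confidence threshold">')
    format_lines = ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    format_lines += [
        f'##FORMAT=<ID={f},Number=1,Type={t},Description="caller metric">'
        for f, t in sorted(format_fields.items())
    ]

    gt_text = {
        Genotype.hom_ref: "0/0",
        Genotype.het: "0/1",
        Genotype.hom_alt: "1/1",
        Genotype.missing: "./.",
    }

    lines = _vcf_header(contigs, info_lines, format_lines, sample="SAMPLE")
    for call in sorted(calls, key=lambda c: (_chrom_sort_key(c.chrom), c.pos, c.id)):
        specs = _specs_of(call.caller, call.svtype)
        qual = "."
        type_token = call.svtype.value
        if call.svtype is SVType.INS and call.id in dup_ids:
            type_token = "DUP"
        info_parts = [
            f"SVTYPE={type_token}",
            f"END={call.end}",
            f"SVLEN={call.svlen if call.svtype is SVType.INS else -call.svlen}",
            "PRECISE" if call.precise else "IMPRECISE",
        ]
        fmt_keys, fmt_vals = ["GT"], [gt_text[call.genotype]]
        for spec in specs:
            value = call.metrics.get(spec.name)
            if spec.source == "QUAL":
                qual = "." if value is None else f"{value:.4f}"
            elif spec.vcf_field in ("PRECISE", "IMPRECISE"):
                continue  # encoded as the flag above
            elif spec.source == "INFO":
                if value is not None:
                    info_parts.append(f"{spec.vcf_field}={value:.4f}")
            else:
                fmt_keys.append(spec.vcf_field)
                fmt_vals.append("." if value is None else f"{value:.4f}")
        filt = "PASS" if call.filter_pass else "LowQual"
        lines.append(
            f"{call.chrom}\t{call.pos}\t{call.id}\tN\t<{type_token}>\t"
            f"{qual}\t{filt}\t{';'.join(info_parts)}\t"
            f"{':'.join(fmt_keys)}\t{':'.join(fmt_vals)}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
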