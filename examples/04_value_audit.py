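"""Value-domain auditing of mapped element pairs.

Two elements that denote the same variable can still disagree on how the
value is stored: different units, different permissible-value lists, or a
different value type altogether.  The audit classifies each valid mapping.
"""

from cdemap import DataElement, Source, audit_pair

pairs = [
    (
        "same volume, different units",
        DataElement("NACC:img:r0001", Source.NACC, "Imaging",
                    "Segmented right hippocampus volume (cc)", unit="cc"),
        DataElement("ADNI:SNT:RHV", Source.ADNI, "UCSF SNT Hippocampal Volumes",
                    "Right Hippocampus Volume", unit="mm3"),
    ),
    (
        "coded yes/no vs yes/no/unknown",
        DataElement("ADNI:GDS:HELP", Source.ADNI, "Geriatric Depression Scale",
                    "8. Do you often feel helpless?", value_codes="1=Yes; 0=No"),
        DataElement("CDE:gds-helpless:r0001", Source.CDE,
                    "Geriatric Depression Scale (GDS) - feel helpless indicator",
                    "Do you often feel helpless?", value_codes="Yes;No;Unknown"),
    ),
    (
        "coded categories vs free numeric count",
        DataElement("NACC:hh:r0001", Source.NACC, "Subject Health History",
                    "Average number of packs smoked per day",
                    value_codes="1=Less than one pack; 2=One to two packs"),
        DataElement("ADNI:MH:PACKS", Source.ADNI, "Medical History",
                    "16a. During periods of smoking, the average number of packs/day",
                    unit="packs"),
    ),
]

for label, a, b in pairs:
    audit = audit_pair(a, b)
    print(f"{label}:")
    print(f"  value types: {audit.type_verdict.value}", end="")
    if audit.unit_verdict:
        print(f"; units: {audit.unit_verdict.value}", end="")
    if audit.value_list_verdict:
        print(f"; value lists: {audit.value_list_verdict.value}", end="")
    print()
print(
    "-> disparate units or value lists mean the mapping is usable only after\n"
    "   value harmonization, even though the variables are the same"
)
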