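"""The severity rule engine: (stage, zone, plus) -> severe / not severe.

Prints the exhaustive 26-row rule table.  Severe rows are exactly: any
staged lesion in zone I, stage 2 in zone II with plus, stage 3 in zone II,
and stage 4 anywhere; `rule_fired` names the first matching rule, which is
what the per-eye evidence trail reports.
"""

from ropmap import SeverityInput, classify, rule_table

table = rule_table()
print(table.to_string(index=False))
print(f"\n{(table.severity == 'severe').sum()} of {len(table)} combinations are severe")

call = classify(SeverityInput(stage=2, zone="II", plus=True))
print(f"example: stage 2, zone II, plus -> {call.severity} via rule {call.rule_fired}")
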