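# Default currency-metabolite / cofactor base ids (compartment suffix
# stripped, case-insensitive).  Override with tag_cofactors(gem, base_ids=...)
# or the --cofactors CLI/config option.
atp
adp
amp
nad
nadh
nadp
nadph
fad
fadh2
coa
accoa
h2o
h
co2
o2
nh4
pi
ppi
so4
q8
q8h2
gthrd
gthox
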