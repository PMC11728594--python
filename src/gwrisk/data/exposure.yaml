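# Residential receptor drawing untreated groundwater as the household supply.
# gwcr: drinking-water intake, L/day; ef: days/year; ed: years; bw: kg;
# at_c / at_nc: averaging times in days (at_nc is a fixed constant, 365 * default ed);
# sa: contacted skin area, cm^2 (hands during household water use);
# t_event: h per contact event; ev: events/day; et_in / et_out: h/day spent
# indoors / outdoors; boil_reduction: fraction of volatile solute removed by boiling.
gwcr: 2.5
ef: 365
ed: 24
bw: 60
at_c: 25550
at_nc: 8760
sa: 1000
t_event: 0.1
ev: 1
et_in: 20
et_out: 4
boil_reduction: 0.6
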