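# Accession -> subgroup map for the reference proteins used to anchor
# subgroup assignment. Best-effort reconstruction; edit freely.
# The packaged at_refs_synthetic.faa contains SYNTHETIC stand-in
# sequences generated by wrkykit.synthetic_data.gen_reference_set;
# replace with real sequences for production use.
AEE85928.1: IId
AAP21276.1: IIe
AAM78067.1: IIa
ANM67410.1: I
AAB63078.1: IId
ABH04558.1: IIe
AEE84006.1: IIc
AEE84546.1: IIb
AEE82969.1: III
AEC10646.1: IIc
ABD57509.1: I
AAQ62425.1: IIc
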