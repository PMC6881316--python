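# Synonymy and species-complex policy for the truffle market audit.
#
# "lenient": a specimen sold under a complex's nominal species name is not a
# mislabel when its molecular assignment is in that complex's accepted set.
# "strict": only an exact canonical match passes.
mode = "lenient"

[synonyms]
# The Burgundy truffle: conspecific trade names.
"T. uncinatum" = "T. aestivum"

[complexes."T. indicum"]
# Asian black truffle complex: three sister lineages sold interchangeably
# under the nominal name. Sale of T. longispinosum as "T. indicum" is
# accepted (sister species, same market class); T. himalayense is not.
members = ["T. indicum", "T. longispinosum", "T. himalayense"]
accepted = ["T. indicum", "T. longispinosum"]
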