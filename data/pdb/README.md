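# Reference crystal structures

The geometry acceptance tests validate catalytic-role distances on two
crystal structures that are not redistributed with this package:

* `2dqa.pdb` — invertebrate-type (I-type) lysozyme, chain A
* `1am7.pdb` — lambda-phage lysozyme

Download them from the Protein Data Bank (https://www.rcsb.org) into this
directory to enable those tests; without the files they report as failing
with an explanatory message.
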