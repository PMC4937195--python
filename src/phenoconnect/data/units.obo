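format-version: 1.2
ontology: phenoconnect-units

[Term]
id: unit:length
name: length unit

[Term]
id: unit:mass
name: mass unit

[Term]
id: unit:volume
name: volume unit

[Term]
id: unit:pressure
name: pressure unit

[Term]
id: unit:time
name: time unit

[Term]
id: unit:meter
name: meter
synonym: "m" EXACT []
synonym: "metre" EXACT []
is_a: unit:length

[Term]
id: unit:centimeter
name: centimeter
synonym: "cm" EXACT []
synonym: "centimetre" EXACT []
is_a: unit:length

[Term]
id: unit:millimeter
name: millimeter
synonym: "mm" EXACT []
synonym: "millimetre" EXACT []
is_a: unit:length

[Term]
id: unit:kilogram
name: kilogram
synonym: "kg" EXACT []
is_a: unit:mass

[Term]
id: unit:gram
name: gram
synonym: "g" EXACT []
synonym: "gr" EXACT []
is_a: unit:mass

[Term]
id: unit:milligram
name: milligram
synonym: "mg" EXACT []
is_a: unit:mass

[Term]
id: unit:liter
name: liter
synonym: "L" EXACT []
synonym: "litre" EXACT []
is_a: unit:volume

[Term]
id: unit:milliliter
name: milliliter
synonym: "mL" EXACT []
synonym: "millilitre" EXACT []
is_a: unit:volume

[Term]
id: unit:mmhg
name: millimeter of mercury
synonym: "mmHg" EXACT []
is_a: unit:pressure

[Term]
id: unit:day
name: day
is_a: unit:time

[Term]
id: unit:week
name: week
is_a: unit:time

[Term]
id: unit:month
name: month
is_a: unit:time

[Term]
id: unit:year
name: year
is_a: unit:time
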