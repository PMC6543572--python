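# demo lexicon: form<TAB>baseform<TAB>part1|part2 (parts optional)
# English inflected forms
complications	complication
failures	failure
failed	fail
failing	fail
fails	fail
incidents	incident
studies	study
studied	study
clips	clip
clipping	clip
clipped	clip
stents	stent
occluders	occluder
implants	implant
implanted	implant
devices	device
risks	risk
events	event
materials	material
alloys	alloy
fractures	fracture
fractured	fracture
broke	break
broken	break
migrated	migrate
migrations	migration
corroded	corrode
corrosion	corrode
reactions	reaction
patients	patient
animals	animal
tests	test
tested	test
# German inflected forms and compounds
komplikationen	komplikation
zwischenfälle	zwischenfall
zwischenfalls	zwischenfall
studien	studie
geräte	gerät
gerätes	gerät
werkstoffe	werkstoff
legierungen	legierung
brüche	bruch
qualitätskontrolle	qualitätskontrolle	qualität|kontrolle
qualitätskontrollen	qualitätskontrolle	qualität|kontrolle
herzschrittmacher	herzschrittmacher	herz|schrittmacher
magenclip	magenclip	magen|clip
gefäßstütze	gefäßstütze	gefäß|stütze
gefäßstützen	gefäßstütze	gefäß|stütze
drahtgeflecht	drahtgeflecht	draht|geflecht
metalllegierung	metalllegierung	metall|legierung
metalllegierungen	metalllegierung	metall|legierung
tierversuch	tierversuch	tier|versuch
tierversuche	tierversuch	tier|versuch
nickeltitan	nickeltitan	nickel|titan
formgedächtnislegierung	formgedächtnislegierung	formgedächtnis|legierung
studienprotokoll	studienprotokoll	studien|protokoll
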