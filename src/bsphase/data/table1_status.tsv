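Population	Species	Lineage	Locus silenced	Methylated?
Pullman	T. dubius	2613-1		NA
Pullman	T. dubius	2613-11		NA
Pullman	T. miscellus	2605-4	TDF44_d	Yes-A/S
Pullman	T. miscellus	2605-7	TDF44_d	Yes-A/S
Pullman	T. miscellus	2605-13	TDF44_d	Yes-A/S
Pullman	T. miscellus	2605-13	S18_d	Yes-A
Pullman	T. miscellus	2605-24	TDF44_d	Yes-A/S
Pullman	T. miscellus	2605-28	TDF44_d	Yes-A/S
Pullman	T. miscellus	2605-46	TDF44_d	Yes-A/S
Moscow	T. pratensis	2608-31		NA
Moscow	T. pratensis	2608-35x		NA
Moscow	T. miscellus	2604-4	TDF44_d	Yes-A/S
Moscow	T. miscellus	2604-11	TDF44_d	Yes-A/S
Moscow	T. miscellus	2604-15	TDF44_d	Yes-A/S
Moscow	T. miscellus	2604-22	T. pratensis genomic copy lost
Moscow	T. miscellus	2604-24	TDF44_d	Yes-A/S
Moscow	T. miscellus	2604-35	TDF44_d	Yes-A/S
Spangle	T. miscellus	2693-7	S3_p	No
Spangle	T. miscellus	2693-8	S3_p	No
Spangle	T. miscellus	2693-14	S3_p	No
Spangle	T. miscellus	2693-14	S18_d	No
Garfield	T. dubius	2687-11		NA
Garfield	T. pratensis	2689-17		NA
Garfield	T. miscellus	2688-3	S2_d	Yes-A/S
Garfield	T. miscellus	2688-3	S3_d	No
Garfield	T. miscellus	2688-3	S18_d	No
Oakesdale	T. miscellus	2671-11	S2_d	Yes-A/S
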