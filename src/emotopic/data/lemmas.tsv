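# Default word -> lemma table (TSV). Covers common regular plurals and a few
# irregular inflections of frequent content words; values are never stopwords
# and never appear as keys, so the table is idempotent.
dogs	dog
cats	cat
babies	baby
children	child
women	woman
men	man
people	person
feet	foot
teeth	tooth
mice	mouse
lives	life
wives	wife
knives	knife
leaves	leaf
loves	love
loved	love
loving	love
likes	like
liked	like
liking	like
wins	win
winning	win
walks	walk
walked	walk
walking	walk
runs	run
running	run
ran	run
talks	talk
talked	talk
talking	talk
says	say
said	say
saying	say
goes	go
going	go
went	go
gets	get
getting	get
got	get
makes	make
making	make
made	make
thinks	think
thinking	think
thought	think
feels	feel
feeling	feel
felt	feel
days	day
years	year
months	month
weeks	week
hours	hour
minutes	minute
friends	friend
families	family
things	thing
words	word
topics	topic
tweets	tweet
strokes	stroke
survivors	survivor
patients	patient
doctors	doctor
hospitals	hospital
games	game
teams	team
players	player
songs	song
books	book
movies	movie
smiles	smile
smiled	smile
smiling	smile
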