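# Irregular inflected forms: two columns, base form then extra form.
# Consulted during easy-list expansion; entries whose base word is not on
# the active list are ignored. '#' starts a comment.
write wrote
write written
be was
be were
be been
be is
be am
be are
become became
begin began
begin begun
break broke
break broken
bring brought
build built
buy bought
catch caught
child children
come came
cut cut
do did
do done
draw drew
draw drawn
drink drank
drink drunk
drive drove
drive driven
eat ate
eat eaten
fall fell
fall fallen
feed fed
feel felt
fight fought
find found
fly flew
fly flown
foot feet
forget forgot
forget forgotten
get got
give gave
give given
go went
go gone
grow grew
grow grown
have had
have has
hear heard
hide hid
hide hidden
hit hit
hold held
hurt hurt
keep kept
know knew
know known
lay laid
lead led
leave left
let let
lose lost
make made
man men
mean meant
meet met
mouse mice
pay paid
put put
read read
ride rode
ride ridden
ring rang
ring rung
run ran
say said
see saw
see seen
sell sold
send sent
shut shut
sing sang
sing sung
sit sat
sleep slept
speak spoke
speak spoken
spend spent
stand stood
swim swam
swim swum
take took
take taken
teach taught
tell told
think thought
throw threw
throw thrown
tooth teeth
understand understood
wake woke
wake woken
wear wore
wear worn
win won
woman women
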