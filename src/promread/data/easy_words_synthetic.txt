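# Synthetic easy-word list (base forms).
# A curated stand-in for classic ~3000-word "easy word" vocabularies of
# terms familiar to young readers; the historical lists are licensed and
# are not redistributed here. One word per line; '#' starts a comment.
# No analysis in this package depends on one particular list version.
a
able
about
above
across
act
add
afraid
after
afternoon
again
against
age
ago
air
all
almost
alone
along
already
also
always
am
an
and
angry
animal
another
answer
any
anyone
anything
apple
are
arm
around
ask
asleep
at
ate
away
baby
back
bad
bag
ball
band
bank
base
basket
bath
be
bean
bear
beat
beautiful
became
because
become
bed
been
before
began
begin
behind
being
believe
bell
belong
below
beside
best
better
between
big
bike
bird
birthday
bit
black
blanket
blow
blue
boat
body
book
born
both
bottle
bottom
bowl
box
boy
bread
break
breakfast
bright
bring
brother
brought
brown
build
burn
bus
busy
but
buy
by
cake
call
came
can
candy
cap
car
card
care
careful
carry
cat
catch
chair
chance
change
chase
cheek
cheese
chicken
child
children
chin
city
class
clean
clear
climb
clock
close
cloth
clothes
cloud
coat
cold
color
come
cook
cool
corn
corner
could
count
country
cover
cow
cry
cup
cut
dad
dance
dark
day
dear
deep
desk
did
die
different
dig
dinner
dish
do
doctor
does
dog
doll
done
door
down
draw
dream
dress
drink
drive
drop
dry
duck
each
ear
early
earth
easy
eat
egg
eight
either
else
empty
end
enjoy
enough
even
evening
ever
every
everyone
everything
eye
face
fair
fall
family
far
farm
fast
fat
father
feed
feel
feet
fell
felt
few
field
fight
fill
find
fine
finger
finish
fire
first
fish
five
fix
floor
flower
fly
follow
food
foot
for
forget
found
four
free
fresh
friend
frog
from
front
fruit
full
fun
funny
game
garden
gave
get
girl
give
glad
glass
go
goat
gold
gone
good
got
grade
grand
grass
gray
great
green
grew
ground
grow
guess
had
hair
half
hand
happen
happy
hard
has
hat
have
he
head
hear
heard
heart
heavy
hello
help
hen
her
here
hers
herself
hid
hide
high
hill
him
himself
his
hit
hold
hole
home
hop
hope
horse
hot
hour
house
how
hug
hundred
hungry
hurry
hurt
i
ice
if
important
in
inside
into
is
it
its
itself
jacket
job
join
joke
jump
just
keep
kept
kick
kid
kind
king
kiss
kitchen
kite
knee
knew
know
lady
lake
land
large
last
late
laugh
lay
lead
leaf
learn
leave
left
leg
let
letter
life
lift
light
like
line
lion
list
listen
little
live
long
look
lost
lot
loud
love
low
lunch
mad
made
make
man
many
map
mark
may
maybe
me
mean
meat
meet
men
met
middle
might
mile
milk
mind
mine
minute
miss
mom
money
monkey
month
moon
more
morning
most
mother
mountain
mouse
mouth
move
much
mud
music
must
my
myself
name
near
neck
need
never
new
next
nice
night
nine
no
noise
none
nose
not
note
nothing
now
number
nurse
of
off
often
old
on
once
one
only
open
or
orange
other
our
out
outside
over
own
page
paint
pair
pan
paper
parent
park
part
party
pass
past
pay
pen
pencil
people
person
pet
pick
picnic
picture
pie
piece
pig
place
plan
plant
play
please
pocket
point
pony
pool
poor
pop
pretty
pull
push
put
queen
question
quick
quiet
quite
rabbit
race
rain
ran
reach
read
ready
real
red
remember
rest
ride
right
ring
river
road
rock
roll
roof
room
rope
round
row
rub
run
sad
safe
said
salt
same
sand
sat
saw
say
school
sea
seat
second
see
seed
seem
seen
self
sell
send
sent
seven
shall
she
sheep
shine
ship
shirt
shoe
shop
short
should
shout
show
shut
sick
side
sign
silly
sing
sister
sit
six
size
skin
sky
sleep
slow
small
smell
smile
snow
so
sock
soft
some
someone
something
song
soon
sorry
sound
soup
speak
spell
spend
spoon
sport
spot
spring
stand
star
start
stay
step
stick
still
stone
stop
store
story
street
strong
such
sudden
summer
sun
supper
sure
sweet
swim
table
tail
take
talk
tall
teach
teacher
team
tell
ten
than
thank
that
the
their
them
then
there
these
they
thing
think
third
this
those
thought
three
through
throw
tie
time
tiny
tired
to
today
toe
together
told
tomorrow
too
took
tooth
top
touch
town
toy
train
tree
trip
truck
true
try
turn
twelve
twenty
two
under
until
up
upon
us
use
very
visit
voice
wait
wake
walk
wall
want
warm
was
wash
watch
water
way
we
wear
week
well
went
were
wet
what
wheel
when
where
which
while
white
who
whole
whose
why
wide
will
win
wind
window
winter
wish
with
without
woke
woman
women
wonder
wood
word
wore
work
world
worry
would
write
wrong
yard
year
yellow
yes
yesterday
yet
you
young
your
yourself
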